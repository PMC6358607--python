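"""Formulation similarity metrics.

Two metrics over equal-length level-index vectors, as used to track how
populations consolidate across generations:

* Hamming distance — the number of factors whose dose level differs;
* Levenshtein-equivalent distance — the sum over factors of absolute
  dose-level differences.  For equal-length sequences insertion/deletion
  edits are meaningless, and each substitution is weighted by how many
  ordinal dose steps apart the two levels are.

Both operate on level indices, not real concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hamming",
    "levenshtein_eq",
    "pairwise_matrix",
    "generation_similarity",
    "DistanceMatrix",
]


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("formulations must be equal-length level vectors")
    return a, b


def hamming(a, b) -> int:
    """Number of factors with unequal dose-level designation."""
    a, b = _check_pair(a, b)
    return int(np.sum(a != b))


def levenshtein_eq(a, b) -> int:
    """Total dose-level discrepancy summed over all factors."""
    a, b = _check_pair(a, b)
    return int(np.sum(np.abs(a - b)))


_METRICS = {"hamming": hamming, "levenshtein_eq": levenshtein_eq}


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str

    @property
    def mean_off_diagonal(self) -> float:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(np.mean(self.values[iu]))

    @property
    def median_off_diagonal(self) -> float:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(np.median(self.values[iu]))

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.labels[i], self.labels[j], int(self.values[i, j])))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "distance"])

    def to_square(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_matrix(formulations, metric: str = "hamming",
                    labels=None) -> DistanceMatrix:
    """Full symmetric distance matrix over a set of formulations."""
    formulations = [tuple(f) for f in formulations]
    if len(formulations) < 2:
        raise ValueError("need at least 2 formulations")
    fn = _METRICS[metric]
    n = len(formulations)
    if labels is None:
        labels = [f"F{i + 1:04d}" for i in range(n)]
    values = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(formulations[i], formulations[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(labels), values=values, metric=metric)


def generation_similarity(population_t, population_t1,
                          metric: str = "hamming") -> dict:
    """Per-target distance between consecutive-generation populations.

    Populations are positionally matched (target i at generation t vs the
    formulation occupying slot i at generation t+1).  Returns the mean
    distance and the fraction of targets carried over unchanged.
    """
    if len(population_t) != len(population_t1):
        raise ValueError("populations must have equal size")
    fn = _METRICS[metric]
    dists = [fn(a, b) for a, b in zip(population_t, population_t1)]
    return {
        "mean_distance": float(np.mean(dists)),
        "carried_fraction": float(np.mean([d == 0 for d in dists])),
        "distances": dists,
    }
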