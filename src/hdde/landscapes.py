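"""In silico evaluators standing in for wet-lab responses.

Two families:

* :class:`BenchmarkLandscape` — the noisy Rosenbrock benchmark on a
  discrete coordinate grid, min-max rescaled so the best grid point scores
  exactly 1.0 (the positive-control analogue) and replicates carry additive
  normal noise on the score scale.
* :class:`SyntheticCellLandscape` — a generative log-linear quadratic
  response surface (intercept, generation block offsets, main, square and
  two-factor interaction effects on coded doses) with lognormal replicate
  noise and left-censoring at a count-sensitivity threshold, emulating
  viable-cell-count readouts.

Plus :func:`grid_extrema_chain_dp`, an exact dynamic-programming oracle for
the grid extrema of the Rosenbrock sum (which couples only adjacent
coordinates, so the grid optimum is a shortest path over a chain).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .space import FactorSpace, Formulation, coded_dose

__all__ = [
    "rosenbrock",
    "BenchmarkLandscape",
    "grid_extrema_chain_dp",
    "SyntheticCellLandscape",
]


def rosenbrock(x) -> float:
    """Sum_{i=1..D-1} [100 (x_{i+1} - x_i^2)^2 + (1 - x_i)^2]."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("rosenbrock needs at least 2 coordinates")
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


# ---------------------------------------------------------------------------
# Benchmark landscape


@dataclass
class BenchmarkLandscape:
    """Noisy Rosenbrock benchmark over a discrete grid.

    Each factor's level indices map to equally spaced real coordinates on
    ``coord_range`` (default [-2, 2], which places the continuous optimum
    at (1, ..., 1) exactly on any 5-level grid).  The deterministic score
    of a formulation is

        s(f) = (f_max - rosenbrock(coords(f))) / (f_max - f_min)

    with f_min/f_max the exact grid extrema, so the problem is a
    maximization with a known ceiling of 1.0; each replicate adds
    Normal(0, noise_sd) on the score scale.
    """

    space: FactorSpace
    coord_range: tuple[float, float] = (-2.0, 2.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.rng = np.random.default_rng(self.seed)
        lo, hi = self.coord_range
        self._grids = [np.linspace(lo, hi, f.n_levels) for f in self.space.factors]
        self.f_min, self.f_max, self.argmin, self.argmax = grid_extrema_chain_dp(self)

    def coords(self, f: Formulation) -> np.ndarray:
        f = self.space.validate(f)
        return np.array([g[k] for g, k in zip(self._grids, f)])

    def score(self, f: Formulation) -> float:
        """Deterministic normalized score in [0, 1]."""
        return (self.f_max - rosenbrock(self.coords(f))) / (self.f_max - self.f_min)

    def response(self, f: Formulation, n_replicates: int,
                 rng: np.random.Generator | None = None) -> list[float]:
        rng = rng or self.rng
        s = self.score(f)
        reps = s + rng.normal(0.0, self.noise_sd, size=n_replicates)
        # responses are response-like quantities: clip at zero
        return [float(max(v, 0.0)) for v in reps]

    # evaluator protocol -----------------------------------------------------
    def evaluate(self, formulations, generation, n_replicates):
        return {tuple(f): self.response(f, n_replicates) for f in formulations}

    def pc(self, generation, n_replicates):
        """The positive-control analogue: the best grid point (score 1.0),
        assayed with the same replicate noise."""
        return self.response(self.argmin, n_replicates)


def grid_extrema_chain_dp(landscape: BenchmarkLandscape):
    """Exact min and max of the Rosenbrock sum over the full grid.

    The objective is a sum of terms coupling coordinates i and i+1 only, so
    dynamic programming over the chain (state = level of factor i) finds
    both extrema in O(D * L^2) regardless of the grid's size.
    """
    grids = landscape._grids
    D = len(grids)

    def term(xi: float, xj: float) -> float:
        return 100.0 * (xj - xi * xi) ** 2 + (1.0 - xi) ** 2

    def solve(best):
        # best is min or max
        cost = {k: 0.0 for k in range(len(grids[0]))}
        back: list[dict[int, int]] = []
        for i in range(D - 1):
            nxt: dict[int, float] = {}
            bp: dict[int, int] = {}
            for kj, xj in enumerate(grids[i + 1]):
                vals = [cost[ki] + term(xi, xj) for ki, xi in enumerate(grids[i])]
                v = best(vals)
                nxt[kj] = v
                bp[kj] = int(vals.index(v))
            cost, _ = nxt, back.append(bp)
        k_last = best(cost, key=cost.get)
        value = cost[k_last]
        levels = [k_last]
        for bp in reversed(back):
            levels.append(bp[levels[-1]])
        levels.reverse()
        return value, tuple(levels)

    f_min, argmin = solve(min)
    f_max, argmax = solve(max)
    return f_min, f_max, argmin, argmax


# ---------------------------------------------------------------------------
# Synthetic cell-response landscape


@dataclass
class SyntheticCellLandscape:
    """Generative quadratic response surface for viable-cell counts.

    Per replicate of formulation f at generation p:

        count = exp(K + G_p + sum_j b_j x_j + sum_{i<j} b_ij x_i x_j
                    + sum_j b_jj x_j^2 + Normal(0, sigma))

    with x = coded doses in [-1, 1].  Counts below ``detection_threshold``
    are reported *at* the threshold with a left-censoring flag.  The
    positive control is a serum-reference culture with fixed log-response
    ``pc_log_response`` (no block offset), so normalized scores land on the
    0-1-ish scale of expansion relative to the serum control.
    """

    space: FactorSpace
    intercept: float
    mains: np.ndarray                      # (D,)
    squares: np.ndarray                    # (D,)
    interactions: np.ndarray               # (D, D) upper-triangular used
    sigma: float = 0.2
    block_offsets: dict[int, float] = field(default_factory=dict)
    detection_threshold: float = 0.0
    pc_log_response: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        D = self.space.D
        self.mains = np.asarray(self.mains, dtype=float).reshape(D)
        self.squares = np.asarray(self.squares, dtype=float).reshape(D)
        self.interactions = np.asarray(self.interactions, dtype=float).reshape(D, D)
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")
        self.rng = np.random.default_rng(self.seed)
        if self.pc_log_response is None:
            self.pc_log_response = self.intercept

    def log_mean(self, f: Formulation, generation: int = 1) -> float:
        """Noise-free exponent K + G_p + linear + interaction + quadratic."""
        x = coded_dose(self.space, f)
        g = self.block_offsets.get(int(generation), 0.0)
        iu = np.triu_indices(self.space.D, k=1)
        inter = float(np.sum(self.interactions[iu] * (np.outer(x, x)[iu])))
        return float(self.intercept + g + self.mains @ x + inter + self.squares @ (x * x))

    def response(self, f: Formulation, generation: int, n_replicates: int,
                 rng: np.random.Generator | None = None):
        """Replicate counts and their left-censoring flags."""
        rng = rng or self.rng
        mu = self.log_mean(f, generation)
        counts = np.exp(mu + rng.normal(0.0, self.sigma, size=n_replicates))
        flags = counts < self.detection_threshold
        counts = np.where(flags, self.detection_threshold, counts)
        return [float(c) for c in counts], [bool(b) for b in flags]

    # evaluator protocol -----------------------------------------------------
    def evaluate_censored(self, formulations, generation, n_replicates):
        responses, censored = {}, {}
        for f in formulations:
            vals, flags = self.response(f, generation, n_replicates)
            responses[tuple(f)] = vals
            censored[tuple(f)] = flags
        return responses, censored

    def evaluate(self, formulations, generation, n_replicates):
        return self.evaluate_censored(formulations, generation, n_replicates)[0]

    def pc(self, generation, n_replicates):
        reps = np.exp(self.pc_log_response
                      + self.rng.normal(0.0, self.sigma, size=n_replicates))
        return [float(v) for v in reps]

    # construction -----------------------------------------------------------
    @classmethod
    def random(cls, space: FactorSpace, seed: int, *,
               n_strong_mains: int = 4, strong_range=(0.4, 0.8),
               weak_main_sd: float = 0.05, n_interactions: int = 10,
               interaction_range=(0.1, 0.2), curvature_range=(0.1, 0.3),
               sigma: float = 0.2, intercept: float = 12.0,
               n_generations: int = 30, block_sd: float = 0.05,
               detection_quantile_offset: float = 3.0) -> "SyntheticCellLandscape":
        """A landscape with a few strong main effects, mild negative
        curvature on those factors, several weak two-factor interactions,
        small generation block offsets and lognormal replicate noise.

        The positive-control log-response is anchored at a greedy
        coordinate-ascent optimum of the noise-free surface (started from
        the best of a seeded 2000-point random probe), so the achievable
        optimum scores near 1.0 relative to the control — mirroring
        expansion normalized to a serum-containing reference.
        """
        rng = np.random.default_rng(seed)
        D = space.D
        mains = rng.normal(0.0, weak_main_sd, size=D)
        strong = rng.choice(D, size=min(n_strong_mains, D), replace=False)
        mains[strong] = rng.uniform(*strong_range, size=strong.size) * rng.choice(
            [-1.0, 1.0], size=strong.size)
        squares = np.zeros(D)
        squares[strong] = -rng.uniform(*curvature_range, size=strong.size)
        inter = np.zeros((D, D))
        iu = np.transpose(np.triu_indices(D, k=1))
        pick = rng.choice(len(iu), size=min(n_interactions, len(iu)), replace=False)
        for idx in pick:
            i, j = iu[idx]
            inter[i, j] = rng.uniform(*interaction_range) * rng.choice([-1.0, 1.0])
        blocks = {p: float(rng.normal(0.0, block_sd)) for p in range(2, n_generations + 1)}
        land = cls(space=space, intercept=float(intercept), mains=mains,
                   squares=squares, interactions=inter, sigma=sigma,
                   block_offsets=blocks, detection_threshold=0.0, seed=seed)
        probe_rng = np.random.default_rng(seed + 1)
        probes = [tuple(int(probe_rng.integers(0, f.n_levels)) for f in space.factors)
                  for _ in range(2000)]
        start = max(probes, key=land.log_mean)
        land.pc_log_response = land.log_mean(_coordinate_ascent(land, start))
        land.detection_threshold = math.exp(intercept - detection_quantile_offset)
        return land

    def noise_free_optimum(self) -> tuple[Formulation, float]:
        """Greedy coordinate-ascent local optimum of the noise-free surface
        (exact for separable surfaces; a strong proxy under weak interactions)."""
        probe_rng = np.random.default_rng(self.seed + 1)
        probes = [tuple(int(probe_rng.integers(0, f.n_levels))
                        for f in self.space.factors) for _ in range(2000)]
        start = max(probes, key=self.log_mean)
        best = _coordinate_ascent(self, start)
        return best, self.log_mean(best)

    # coefficient CSV round trip ----------------------------------------------
    def to_csv(self, path) -> None:
        names = [f.name for f in self.space.factors]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["term", "coefficient"])
            w.writerow(["intercept", self.intercept])
            w.writerow(["sigma", self.sigma])
            w.writerow(["detection_threshold", self.detection_threshold])
            w.writerow(["pc_log_response", self.pc_log_response])
            for p, g in sorted(self.block_offsets.items()):
                w.writerow([f"block[{p}]", g])
            for n, b in zip(names, self.mains):
                w.writerow([n, b])
            for n, b in zip(names, self.squares):
                w.writerow([f"{n}^2", b])
            for i in range(self.space.D):
                for j in range(i + 1, self.space.D):
                    if self.interactions[i, j] != 0.0:
                        w.writerow([f"{names[i]}:{names[j]}", self.interactions[i, j]])

def _coordinate_ascent(land: "SyntheticCellLandscape", start) -> tuple:
    """Cycle over factors, moving each to its best level, until stable."""
    cur = list(start)
    improved = True
    while improved:
        improved = False
        for j, fac in enumerate(land.space.factors):
            best_k, best_v = cur[j], land.log_mean(tuple(cur))
            for k in range(fac.n_levels):
                if k == cur[j]:
                    continue
                cand = list(cur)
                cand[j] = k
                v = land.log_mean(tuple(cand))
                if v > best_v:
                    best_k, best_v = k, v
            if best_k != cur[j]:
                cur[j] = best_k
                improved = True
    return tuple(cur)


def _landscape_from_csv(cls, path, space: FactorSpace, seed: int = 0):
    """Rebuild a :class:`SyntheticCellLandscape` from its coefficient CSV."""
    names = {f.name: j for j, f in enumerate(space.factors)}
    D = space.D
    mains = np.zeros(D)
    squares = np.zeros(D)
    inter = np.zeros((D, D))
    blocks: dict[int, float] = {}
    meta = {"intercept": 0.0, "sigma": 0.2, "detection_threshold": 0.0,
            "pc_log_response": None}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            term, coef = row["term"], float(row["coefficient"])
            if term in meta:
                meta[term] = coef
            elif term.startswith("block["):
                blocks[int(term[6:-1])] = coef
            elif term.endswith("^2"):
                squares[names[term[:-2]]] = coef
            elif ":" in term:
                a, b = term.split(":")
                i, j = sorted((names[a], names[b]))
                inter[i, j] = coef
            else:
                mains[names[term]] = coef
    return cls(space=space, intercept=meta["intercept"], mains=mains,
               squares=squares, interactions=inter, sigma=meta["sigma"],
               block_offsets=blocks,
               detection_threshold=meta["detection_threshold"],
               pc_log_response=meta["pc_log_response"], seed=seed)


SyntheticCellLandscape.from_csv = classmethod(_landscape_from_csv)
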