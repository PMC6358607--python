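"""Discrete factor-dose search space and formulation encoding.

A *factor* is one media supplement (cytokine, small molecule, nutrient)
varied across an ordered grid of dose levels; a *formulation* is one choice
of level per factor — a single point in the discrete search space.  Level
indices are 0-based everywhere inside the package; human-facing CSVs use
1-based levels alongside the real concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Factor",
    "FactorSpace",
    "Formulation",
    "coded_dose",
    "decode_coded",
    "total_combinations",
    "random_formulation",
    "load_space",
    "save_space",
]


class InvalidFormulationError(ValueError):
    """A level vector does not fit the factor space."""


@dataclass(frozen=True)
class Factor:
    """One supplement with an ascending grid of real dose concentrations."""

    name: str
    dose_levels: tuple[float, ...]
    unit: str = ""

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.dose_levels)
        object.__setattr__(self, "dose_levels", levels)
        if len(levels) < 2:
            raise ValueError(f"factor {self.name!r}: at least 2 dose levels required")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"factor {self.name!r}: dose levels must be strictly ascending")

    @property
    def n_levels(self) -> int:
        return len(self.dose_levels)


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of factors; ``D`` is the search dimensionality."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        object.__setattr__(self, "factors", factors)
        if not factors:
            raise ValueError("factor space needs at least one factor")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    @property
    def D(self) -> int:
        return len(self.factors)

    @property
    def n_levels(self) -> np.ndarray:
        return np.array([f.n_levels for f in self.factors], dtype=np.int64)

    def validate(self, levels) -> tuple[int, ...]:
        """Return ``levels`` as a tuple after bounds checking."""
        levels = tuple(int(v) for v in levels)
        if len(levels) != self.D:
            raise InvalidFormulationError(
                f"expected {self.D} levels, got {len(levels)}"
            )
        for j, (lev, fac) in enumerate(zip(levels, self.factors)):
            if not 0 <= lev < fac.n_levels:
                raise InvalidFormulationError(
                    f"factor {fac.name!r} (position {j}): level {lev} outside [0, {fac.n_levels - 1}]"
                )
        return levels

    def concentrations(self, levels) -> tuple[float, ...]:
        levels = self.validate(levels)
        return tuple(f.dose_levels[k] for f, k in zip(self.factors, levels))


# A formulation is simply a tuple of 0-based level indices; keeping it a
# plain tuple makes it hashable (the evaluation library keys on it).
Formulation = tuple[int, ...]


def coded_dose(space: FactorSpace, levels) -> np.ndarray:
    """Map level indices linearly onto the coded-dose scale [-1, 1].

    A factor with L levels maps index k to 2k/(L-1) - 1, so the lowest
    level codes to -1 and the highest to +1 (the convention used by the
    quadratic response-surface model).
    """
    levels = space.validate(levels)
    n = space.n_levels
    return 2.0 * np.asarray(levels, dtype=float) / (n - 1) - 1.0


def decode_coded(space: FactorSpace, coded) -> Formulation:
    """Inverse of :func:`coded_dose` (exact for on-grid coded values)."""
    coded = np.asarray(coded, dtype=float)
    n = space.n_levels
    idx = np.rint((coded + 1.0) * (n - 1) / 2.0).astype(int)
    return space.validate(idx)


def total_combinations(space: FactorSpace) -> int:
    """Exact number of formulations in the full grid (python int, no overflow)."""
    return math.prod(f.n_levels for f in space.factors)


def random_formulation(space: FactorSpace, rng: np.random.Generator) -> Formulation:
    """Draw each factor's level uniformly and independently."""
    return tuple(int(rng.integers(0, f.n_levels)) for f in space.factors)


# ---------------------------------------------------------------------------
# Config-file round trip


def save_space(space: FactorSpace, path) -> None:
    doc = {
        "factors": [
            {"name": f.name, "unit": f.unit, "dose_levels": list(f.dose_levels)}
            for f in space.factors
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_space(path) -> FactorSpace:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    factors = tuple(
        Factor(name=d["name"], dose_levels=tuple(d["dose_levels"]), unit=d.get("unit", ""))
        for d in doc["factors"]
    )
    return FactorSpace(factors)


def example_space(D: int = 15, n_levels: int = 6) -> FactorSpace:
    """A generic D-factor space with ``n_levels`` doses per factor.

    Dose grids are geometric (0 excluded) in arbitrary units; only the
    ordinal structure matters to the optimizer.
    """
    factors = tuple(
        Factor(name=f"factor_{j + 1:02d}", dose_levels=tuple(10.0 * 2.0**k for k in range(n_levels)), unit="ng/mL")
        for j in range(D)
    )
    return FactorSpace(factors)


def mixed_level_space(level_counts, prefix: str = "factor") -> FactorSpace:
    """A space with heterogeneous per-factor level counts."""
    factors = tuple(
        Factor(
            name=f"{prefix}_{j + 1:02d}",
            dose_levels=tuple(1.0 * 3.0**k for k in range(L)),
            unit="ng/mL",
        )
        for j, L in enumerate(level_counts)
    )
    return FactorSpace(factors)
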