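"""High-dimensional differential evolution (HD-DE) over discrete dose grids.

The engine runs classic rand/1/bin differential evolution on dose-level
indices, with four extensions for noisy, expensive biological responses:

* replicate-aware selection — a trial replaces its target only when the
  one-sided exact rank-sum test on replicate responses is significant;
* a persistent, deduplicating evaluation library — formulations seen before
  are never re-assayed, their stored replicates are reused;
* competition against best encountered plus clearing/niching of the
  candidate solution set, with replacements perturbed from root members;
* an adaptive parameter schedule — the mutation factor F drops from 1.0 to
  0.5 on score convergence, after which the crossover rate CR drops from
  0.5 to 0.25 once populations largely stop changing.

The generation loop is split into :meth:`HDDERun.propose` (which
formulations need responses next) and :meth:`HDDERun.ingest` (responses in,
selection and bookkeeping out).  This is what lets the same engine drive
both in silico evaluators and a CSV-mediated wet-lab loop, with a JSON
checkpoint in between.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .space import (
    FactorSpace,
    Formulation,
    InvalidFormulationError,
    random_formulation,
)

__all__ = [
    "EngineConfig",
    "EvaluationLibrary",
    "CandidateSolutionSet",
    "HDDERun",
    "population_size",
    "mutate",
    "crossover",
    "quantize",
    "normalized_score",
    "select",
    "perturb_root",
    "detect_convergence",
    "run",
]

PC_KEY = "PC"  # positive-control identifier in the library


class ControlFailureError(ValueError):
    """Positive-control responses are unusable (mean <= 0)."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class EngineConfig:
    """Tunable parameters of the closed-loop optimizer.

    Defaults follow the published schedule: F = 1 and CR = 0.5 initially;
    F is halved on convergence of the overall score, then CR drops to 0.25
    once at least half of the elements of the average target are carried
    between consecutive generations.  Population size is 3*D plus any
    extra formulations the assay capacity allows.
    """

    F_init: float = 1.0
    F_reduced: float = 0.5
    CR_init: float = 0.5
    CR_reduced: float = 0.25
    extra_population: int = 0
    replicates: int = 3
    alpha: float = 0.10            # one-sided rank-sum significance level
    clearing_fraction: float = 0.10
    compete_margin: float = 1.0    # in units of pooled repeat-score SD
    convergence_tol: float = 0.05
    convergence_window: int = 2
    carried_stop_fraction: float = 0.9
    early_stop: bool = True       # False: run the full generation budget
    max_generations: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.F_reduced <= self.F_init):
            raise ValueError("require 0 < F_reduced <= F_init")
        if not (0 < self.CR_reduced <= self.CR_init <= 1):
            raise ValueError("require 0 < CR_reduced <= CR_init <= 1")
        if not (0 < self.clearing_fraction < 1):
            raise ValueError("require 0 < clearing_fraction < 1")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates are needed for rank-sum selection")


def population_size(D: int, extra: int = 0) -> int:
    """Population sizing rule NP = 3*D + extra."""
    if D < 1 or extra < 0:
        raise ValueError("need D >= 1 and extra >= 0")
    return 3 * D + extra


# ---------------------------------------------------------------------------
# Evaluation library


@dataclass
class LibraryEntry:
    values: list[float] = field(default_factory=list)
    generations: list[int] = field(default_factory=list)
    censored: list[bool] = field(default_factory=list)


class EvaluationLibrary:
    """Deduplicated archive of every tested formulation with its replicates.

    Re-evaluating a previously seen formulation appends replicates without
    raising ``unique_count``.  Positive-control responses are stored apart
    and excluded from the count.
    """

    def __init__(self) -> None:
        self._records: dict[Formulation, LibraryEntry] = {}
        self._pc: LibraryEntry = LibraryEntry()

    # -- recording ---------------------------------------------------------
    def add(self, levels: Formulation, values: Sequence[float], generation: int,
            censored: Sequence[bool] | None = None) -> None:
        values = [float(v) for v in values]
        if not values:
            raise ValueError("at least one replicate value is required")
        if any(not math.isfinite(v) or v < 0 for v in values):
            raise ValueError("replicate values must be finite and nonnegative")
        if censored is None:
            censored = [False] * len(values)
        entry = self._records.setdefault(tuple(levels), LibraryEntry())
        entry.values.extend(values)
        entry.generations.extend([generation] * len(values))
        entry.censored.extend(bool(c) for c in censored)

    def add_pc(self, values: Sequence[float], generation: int) -> None:
        values = [float(v) for v in values]
        self._pc.values.extend(values)
        self._pc.generations.extend([generation] * len(values))
        self._pc.censored.extend([False] * len(values))

    # -- queries -----------------------------------------------------------
    def __contains__(self, levels) -> bool:
        return tuple(levels) in self._records

    def get(self, levels) -> LibraryEntry | None:
        return self._records.get(tuple(levels))

    def replicate_values(self, levels) -> list[float]:
        entry = self._records[tuple(levels)]
        return list(entry.values)

    @property
    def unique_count(self) -> int:
        return len(self._records)

    @property
    def pc_values(self) -> list[float]:
        return list(self._pc.values)

    def pc_mean(self) -> float:
        if not self._pc.values:
            raise ControlFailureError("no positive-control responses recorded")
        m = float(np.mean(self._pc.values))
        if m <= 0:
            raise ControlFailureError("positive-control mean response is <= 0")
        return m

    def score(self, levels) -> float:
        """Mean response normalized to the pooled positive-control mean."""
        return float(np.mean(self._records[tuple(levels)].values)) / self.pc_mean()

    def items(self):
        return self._records.items()

    def pooled_repeat_sd(self, fallback: float = 0.05) -> float:
        """Inter-experimental variability estimate.

        Pools the across-generation SD of per-generation mean scores for
        formulations evaluated in >= 2 generations; ``fallback`` when no
        formulation has repeats yet.
        """
        pc = self.pc_mean()
        variances: list[float] = []
        weights: list[int] = []
        for entry in self._records.values():
            gens = sorted(set(entry.generations))
            if len(gens) < 2:
                continue
            per_gen = [
                np.mean([v for v, g in zip(entry.values, entry.generations) if g == gen]) / pc
                for gen in gens
            ]
            variances.append(float(np.var(per_gen, ddof=1)))
            weights.append(len(gens) - 1)
        if not variances:
            return fallback
        pooled = math.sqrt(
            sum(v * w for v, w in zip(variances, weights)) / sum(weights)
        )
        return pooled if pooled > 0 else fallback

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "records": [
                {"levels": list(k), "values": e.values,
                 "generations": e.generations, "censored": e.censored}
                for k, e in self._records.items()
            ],
            "pc": {"values": self._pc.values, "generations": self._pc.generations},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationLibrary":
        lib = cls()
        for rec in doc["records"]:
            entry = LibraryEntry(
                values=list(rec["values"]),
                generations=list(rec["generations"]),
                censored=list(rec["censored"]),
            )
            lib._records[tuple(rec["levels"])] = entry
        lib._pc = LibraryEntry(
            values=list(doc["pc"]["values"]),
            generations=list(doc["pc"]["generations"]),
            censored=[False] * len(doc["pc"]["values"]),
        )
        return lib


# ---------------------------------------------------------------------------
# Candidate solution set


class CandidateSolutionSet:
    """Best formulations encountered so far, maintained by competition.

    Scores are always read from the evaluation library so that they reflect
    all replicates accumulated to date.
    """

    def __init__(self, capacity: int) -> None:
        self.capacity = int(capacity)
        self.members: list[Formulation] = []

    def scores(self, library: EvaluationLibrary) -> list[float]:
        return [library.score(m) for m in self.members]

    def best(self, library: EvaluationLibrary) -> tuple[Formulation, float]:
        scores = self.scores(library)
        i = int(np.argmax(scores))
        return self.members[i], scores[i]

    def compete_best(self, candidate: Formulation, library: EvaluationLibrary,
                     margin: float = 1.0, sd_fallback: float = 0.05) -> bool:
        """Admit ``candidate`` only if it beats the weakest member by more
        than ``margin`` times the estimated inter-experimental variability.

        Returns True when the set changed.
        """
        candidate = tuple(candidate)
        if candidate in self.members:
            return False
        if not self.members:
            self.members.append(candidate)
            return True
        scores = self.scores(library)
        cand_score = library.score(candidate)
        low_i = int(np.argmin(scores))
        sd = library.pooled_repeat_sd(fallback=sd_fallback)
        if cand_score <= scores[low_i] + margin * sd:
            return False
        if len(self.members) >= self.capacity:
            del self.members[low_i]
        self.members.append(candidate)
        return True

    def clearing(self, library: EvaluationLibrary, clearing_fraction: float) -> list[Formulation]:
        """Remove members scoring below (1 - fraction) x best; return them."""
        if not self.members:
            return []
        scores = self.scores(library)
        cutoff = (1.0 - clearing_fraction) * max(scores)
        cleared = [m for m, s in zip(self.members, scores) if s < cutoff]
        self.members = [m for m, s in zip(self.members, scores) if s >= cutoff]
        return cleared

    def pick_root(self, library: EvaluationLibrary, rng: np.random.Generator) -> Formulation:
        """Stochastic, score-weighted choice of a surviving root member."""
        scores = np.asarray(self.scores(library), dtype=float)
        w = np.clip(scores, 0.0, None)
        if w.sum() <= 0:
            w = np.ones_like(w)
        return self.members[int(rng.choice(len(self.members), p=w / w.sum()))]

    def to_dict(self) -> dict:
        return {"capacity": self.capacity, "members": [list(m) for m in self.members]}

    @classmethod
    def from_dict(cls, doc: dict) -> "CandidateSolutionSet":
        cs = cls(doc["capacity"])
        cs.members = [tuple(m) for m in doc["members"]]
        return cs


# ---------------------------------------------------------------------------
# DE operators


def mutate(i: int, population: Sequence[Formulation], F: float,
           rng: np.random.Generator) -> np.ndarray:
    """rand/1 donor: x_r1 + F * (x_r2 - x_r3) on level indices as reals."""
    NP = len(population)
    if NP < 4:
        raise ValueError("rand/1 mutation needs a population of at least 4")
    choices = [j for j in range(NP) if j != i]
    r1, r2, r3 = rng.choice(choices, size=3, replace=False)
    x1 = np.asarray(population[r1], dtype=float)
    x2 = np.asarray(population[r2], dtype=float)
    x3 = np.asarray(population[r3], dtype=float)
    return x1 + F * (x2 - x3)


def crossover(target: Sequence[int], donor: np.ndarray, CR: float,
              rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with one forced donor position."""
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if target.shape != donor.shape:
        raise ValueError("target and donor must have equal length")
    D = target.size
    take = rng.random(D) < CR
    take[int(rng.integers(0, D))] = True
    return np.where(take, donor, target)


def quantize(space: FactorSpace, vec) -> Formulation:
    """Round each coordinate to the nearest level (half away from zero),
    then clip to the factor's valid index range."""
    vec = np.asarray(vec, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite coordinate in trial vector")
    rounded = np.sign(vec) * np.floor(np.abs(vec) + 0.5)
    clipped = np.clip(rounded, 0, space.n_levels - 1)
    return tuple(int(v) for v in clipped)


def normalized_score(records: Sequence[float], pc_records: Sequence[float]) -> float:
    """Mean response over mean positive-control response (PC scores 1.0)."""
    pc_mean = float(np.mean(pc_records))
    if pc_mean <= 0:
        raise ControlFailureError("positive-control mean response is <= 0")
    return float(np.mean(records)) / pc_mean


def select(target_records: Sequence[float], trial_records: Sequence[float],
           alpha: float) -> str:
    """Replicate-aware selection between incumbent target and trial.

    The trial advances only when its median response exceeds the target's
    AND the one-sided exact Wilcoxon rank-sum test rejects at ``alpha``.
    Ties retain the incumbent.
    """
    if len(target_records) < 2 or len(trial_records) < 2:
        raise ValueError("selection needs >= 2 replicates per formulation")
    if np.median(trial_records) <= np.median(target_records):
        return "target"
    pooled = list(target_records) + list(trial_records)
    if len(set(pooled)) == len(pooled):
        res = stats.mannwhitneyu(trial_records, target_records,
                                 alternative="greater", method="exact")
    else:
        # the exact null distribution ignores ties; the permutation test
        # enumerates all group assignments and is exact with midranks
        res = stats.mannwhitneyu(trial_records, target_records,
                                 alternative="greater",
                                 method=stats.PermutationMethod(random_state=0))
    return "trial" if res.pvalue < alpha else "target"


def perturb_root(root: Formulation, space: FactorSpace,
                 rng: np.random.Generator) -> Formulation:
    """Deterministically enumerate all single-factor +/-1-level neighbors of
    ``root`` (clipped to the grid, excluding root), then pick one uniformly."""
    root = space.validate(root)
    pool: list[Formulation] = []
    for j, fac in enumerate(space.factors):
        for step in (-1, +1):
            k = root[j] + step
            if 0 <= k < fac.n_levels:
                cand = list(root)
                cand[j] = k
                pool.append(tuple(cand))
    if not pool:
        raise RuntimeError("empty perturbation pool — degenerate factor space")
    return pool[int(rng.integers(0, len(pool)))]


def detect_convergence(score_history: Sequence[float], tol: float, window: int) -> bool:
    """True when the relative change of the best score is below ``tol`` for
    each of the last ``window`` generation steps."""
    if len(score_history) < window + 1:
        return False
    recent = list(score_history)[-(window + 1):]
    for a, b in zip(recent, recent[1:]):
        denom = abs(a) if a != 0 else 1.0
        if abs(b - a) / denom >= tol:
            return False
    return True


# ---------------------------------------------------------------------------
# The closed loop


@dataclass
class TraceRow:
    generation: int
    best_score: float
    mean_score: float
    n_improved: int
    n_carried: int
    F: float
    CR: float
    unique_count: int


class HDDERun:
    """State machine for one optimization campaign.

    Usage::

        run = HDDERun(space, config)
        while not run.finished:
            batch = run.propose()                    # formulations + PC
            responses = {f: assay(f) for f in batch.formulations}
            run.ingest(responses, pc=assay_pc())

    ``propose`` is idempotent for a fixed state (the pending batch is part
    of the checkpoint), which is what makes the CSV lab-in-the-loop mode
    safe to re-run.
    """

    def __init__(self, space: FactorSpace, config: EngineConfig) -> None:
        self.space = space
        self.config = config
        self.NP = population_size(space.D, config.extra_population)
        if self.NP < 4:
            raise ValueError("population too small for rand/1 mutation (NP >= 4)")
        self.rng = np.random.default_rng(config.seed)
        self.library = EvaluationLibrary()
        self.cset = CandidateSolutionSet(capacity=self.NP)
        self.generation = 0          # completed generations
        self.F = config.F_init
        self.CR = config.CR_init
        self.f_reduced = False
        self.score_history: list[float] = []   # best candidate score per generation
        self.carried_history: list[int] = []
        self.trace: list[TraceRow] = []
        self.population: list[Formulation] = [
            random_formulation(space, self.rng) for _ in range(self.NP)
        ]
        self.prev_population: list[Formulation] | None = None
        self.population_history: list[list[Formulation]] = []
        self.pending_trials: list[Formulation] | None = None  # per-target trials (gen >= 2)
        self.finished = False
        self.termination_reason: str | None = None

    # -- proposal ----------------------------------------------------------

    def propose(self) -> "ProposalBatch":
        """Return the batch of formulations needing fresh responses for the
        next generation (plus the positive control, always re-assayed)."""
        if self.finished:
            raise RuntimeError("run already terminated")
        if self.generation >= 1 and self.pending_trials is None:
            self.pending_trials = self._make_trials()
        need: list[Formulation] = []
        seen: set[Formulation] = set()

        def want(f: Formulation) -> None:
            if f not in self.library and f not in seen:
                seen.add(f)
                need.append(f)

        for f in self.population:          # gen-1 members / injected replacements
            want(f)
        if self.pending_trials is not None:
            for tgt, trial in zip(self.population, self.pending_trials):
                if trial != tgt:
                    want(trial)
        return ProposalBatch(generation=self.generation + 1, formulations=need,
                             replicates=self.config.replicates)

    def _make_trials(self) -> list[Formulation]:
        trials = []
        for i, target in enumerate(self.population):
            donor = mutate(i, self.population, self.F, self.rng)
            trial_vec = crossover(target, donor, self.CR, self.rng)
            trials.append(quantize(self.space, trial_vec))
        return trials

    # -- ingestion ---------------------------------------------------------

    def ingest(self, responses: dict[Formulation, Sequence[float]],
               pc: Sequence[float],
               censored: dict[Formulation, Sequence[bool]] | None = None) -> None:
        """Record a generation's responses and complete the generation:
        selection, candidate-set competition, clearing, parameter adaptation
        and the termination check."""
        if self.finished:
            raise RuntimeError("run already terminated")
        batch = self.propose()
        gen = batch.generation
        missing = [f for f in batch.formulations if tuple(f) not in
                   {tuple(k) for k in responses}]
        if missing:
            raise KeyError(f"responses missing for {len(missing)} formulations: "
                           f"{missing[:3]}...")
        censored = censored or {}
        for f, vals in responses.items():
            f = tuple(f)
            self.space.validate(f)
            self.library.add(f, vals, gen, censored.get(f))
        self.library.add_pc(pc, gen)

        if gen == 1:
            self._complete_initial_generation()
        else:
            self._complete_de_generation()

    def _complete_initial_generation(self) -> None:
        cfg = self.config
        for f in self.population:
            self.cset.compete_best(f, self.library, margin=cfg.compete_margin)
        self.generation = 1
        self.prev_population = list(self.population)
        self.population_history.append(list(self.population))
        best_score = (self.cset.best(self.library)[1] if self.cset.members
                      else float("nan"))
        self.score_history.append(best_score)
        mean_score = float(np.mean([self.library.score(f) for f in self.population]))
        self._record_trace(n_improved=0, n_carried=0,
                           F=self.F, CR=self.CR, best_score=best_score,
                           mean_score=mean_score)
        if cfg.max_generations <= 1:
            self._terminate("max_generations")

    def _complete_de_generation(self) -> None:
        cfg = self.config
        gen = self.generation + 1
        trials = self.pending_trials
        assert trials is not None
        F_used, CR_used = self.F, self.CR
        new_pop: list[Formulation] = []
        n_improved = 0
        for target, trial in zip(self.population, trials):
            if trial == target:
                new_pop.append(target)
                continue
            winner = select(self.library.replicate_values(target),
                            self.library.replicate_values(trial), cfg.alpha)
            if winner == "trial":
                new_pop.append(trial)
                n_improved += 1
            else:
                new_pop.append(target)
            self.cset.compete_best(trial, self.library, margin=cfg.compete_margin)

        self.prev_population = list(self.population)
        self.population = new_pop
        self.pending_trials = None
        self.generation = gen
        best_score = (self.cset.best(self.library)[1] if self.cset.members
                      else float("nan"))
        mean_score = float(np.mean([self.library.score(f) for f in new_pop]))
        self.score_history.append(best_score)
        self._adapt_parameters()
        if self.f_reduced:
            self._apply_clearing()
        # carried = population slots unchanged between consecutive actual
        # populations, so clearing injections count as turnover
        n_carried = sum(a == b for a, b in zip(self.prev_population, self.population))
        self.carried_history.append(n_carried)
        self.population_history.append(list(self.population))
        self._record_trace(n_improved=n_improved, n_carried=n_carried,
                           F=F_used, CR=CR_used, best_score=best_score,
                           mean_score=mean_score)
        self._check_termination()

    def _record_trace(self, n_improved: int, n_carried: int,
                      F: float, CR: float, best_score: float,
                      mean_score: float) -> None:
        self.trace.append(TraceRow(
            generation=self.generation,
            best_score=best_score,
            mean_score=mean_score,
            n_improved=n_improved,
            n_carried=n_carried,
            F=F,
            CR=CR,
            unique_count=self.library.unique_count,
        ))

    def _adapt_parameters(self) -> None:
        cfg = self.config
        if not self.f_reduced and detect_convergence(
                self.score_history, cfg.convergence_tol, cfg.convergence_window):
            self.F = cfg.F_reduced
            self.f_reduced = True
        if self.f_reduced and self.CR > cfg.CR_reduced and self.prev_population:
            unchanged = [
                sum(a == b for a, b in zip(prev, cur))
                for prev, cur in zip(self.prev_population, self.population)
            ]
            if np.mean(unchanged) >= self.space.D / 2:
                self.CR = cfg.CR_reduced

    def _apply_clearing(self) -> None:
        cfg = self.config
        cleared = self.cset.clearing(self.library, cfg.clearing_fraction)
        if not cleared or not self.cset.members:
            return
        replacements = []
        for _ in cleared:
            root = self.cset.pick_root(self.library, self.rng)
            replacements.append(perturb_root(root, self.space, self.rng))
        # inject replacements over the lowest-scoring population slots
        scores = np.array([self.library.score(f) for f in self.population])
        worst = np.argsort(scores)[: len(replacements)]
        for slot, repl in zip(worst, replacements):
            self.population[int(slot)] = repl

    def _check_termination(self) -> None:
        cfg = self.config
        if self.generation >= cfg.max_generations:
            self._terminate("max_generations")
            return
        w = cfg.convergence_window
        if cfg.early_stop and self.f_reduced and len(self.carried_history) >= w:
            recent = self.carried_history[-w:]
            if all(c >= cfg.carried_stop_fraction * self.NP for c in recent):
                self._terminate("population_converged")

    def _terminate(self, reason: str) -> None:
        self.finished = True
        self.termination_reason = reason

    # -- checkpointing -----------------------------------------------------

    def to_checkpoint(self) -> dict:
        return {
            "schema": "hdde-checkpoint-v1",
            "config": asdict(self.config),
            "space": {
                "factors": [
                    {"name": f.name, "unit": f.unit, "dose_levels": list(f.dose_levels)}
                    for f in self.space.factors
                ]
            },
            "generation": self.generation,
            "F": self.F,
            "CR": self.CR,
            "f_reduced": self.f_reduced,
            "score_history": self.score_history,
            "carried_history": self.carried_history,
            "population": [list(f) for f in self.population],
            "prev_population": ([list(f) for f in self.prev_population]
                                if self.prev_population is not None else None),
            "population_history": [[list(f) for f in pop]
                                   for pop in self.population_history],
            "pending_trials": ([list(f) for f in self.pending_trials]
                               if self.pending_trials is not None else None),
            "finished": self.finished,
            "termination_reason": self.termination_reason,
            "rng_state": _jsonable(self.rng.bit_generator.state),
            "library": self.library.to_dict(),
            "cset": self.cset.to_dict(),
            "trace": [asdict(r) for r in self.trace],
        }

    @classmethod
    def from_checkpoint(cls, doc: dict) -> "HDDERun":
        from .space import Factor, FactorSpace
        if doc.get("schema") != "hdde-checkpoint-v1":
            raise ValueError("unrecognized or corrupt checkpoint")
        space = FactorSpace(tuple(
            Factor(name=f["name"], dose_levels=tuple(f["dose_levels"]), unit=f.get("unit", ""))
            for f in doc["space"]["factors"]
        ))
        run = cls.__new__(cls)
        run.space = space
        run.config = EngineConfig(**doc["config"])
        run.NP = population_size(space.D, run.config.extra_population)
        run.rng = np.random.default_rng()
        run.rng.bit_generator.state = _unjsonable(doc["rng_state"])
        run.library = EvaluationLibrary.from_dict(doc["library"])
        run.cset = CandidateSolutionSet.from_dict(doc["cset"])
        run.generation = doc["generation"]
        run.F = doc["F"]
        run.CR = doc["CR"]
        run.f_reduced = doc["f_reduced"]
        run.score_history = list(doc["score_history"])
        run.carried_history = list(doc["carried_history"])
        run.population = [tuple(f) for f in doc["population"]]
        run.prev_population = ([tuple(f) for f in doc["prev_population"]]
                               if doc["prev_population"] is not None else None)
        run.population_history = [[tuple(f) for f in pop]
                                  for pop in doc.get("population_history", [])]
        run.pending_trials = ([tuple(f) for f in doc["pending_trials"]]
                              if doc["pending_trials"] is not None else None)
        run.finished = doc["finished"]
        run.termination_reason = doc["termination_reason"]
        run.trace = [TraceRow(**r) for r in doc["trace"]]
        return run

    def save_checkpoint(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_checkpoint(), fh)

    @classmethod
    def load_checkpoint(cls, path) -> "HDDERun":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
        return cls.from_checkpoint(doc)


@dataclass
class ProposalBatch:
    generation: int
    formulations: list[Formulation]
    replicates: int


def _jsonable(obj):
    """numpy rng state contains ints > 2**53 and arrays; stringify safely."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": [int(v) for v in obj.tolist()]}
    if isinstance(obj, (np.integer,)):
        return {"__int__": str(int(obj))}
    if isinstance(obj, int) and abs(obj) > 2**53:
        return {"__int__": str(obj)}
    return obj


def _unjsonable(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.array(obj["__ndarray__"], dtype=np.uint32)
        if "__int__" in obj:
            return int(obj["__int__"])
        return {k: _unjsonable(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# Convenience driver


def run(space: FactorSpace, config: EngineConfig, evaluator) -> HDDERun:
    """Drive a full campaign against an in silico evaluator.

    ``evaluator`` must provide ``evaluate(formulations, generation,
    n_replicates) -> {formulation: [replicates]}`` (optionally with a
    parallel ``censored`` mapping via ``evaluate_censored``) and
    ``pc(generation, n_replicates) -> [replicates]``.
    """
    state = HDDERun(space, config)
    while not state.finished:
        batch = state.propose()
        if hasattr(evaluator, "evaluate_censored"):
            responses, censored = evaluator.evaluate_censored(
                batch.formulations, batch.generation, batch.replicates)
        else:
            responses = evaluator.evaluate(
                batch.formulations, batch.generation, batch.replicates)
            censored = None
        pc = evaluator.pc(batch.generation, batch.replicates)
        state.ingest(responses, pc=pc, censored=censored)
    return state
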