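"""Run configuration, CSV exchange formats and campaign drivers.

This layer replaces the liquid-handler / cytometer file hand-off of a
robotic wet lab with three plain-text artifacts:

* recipe CSV  — algorithm-proposed formulations for the next generation,
  with 1-based dose levels and real concentrations side by side, plus
  positive-control (PC) rows;
* responses CSV — replicate viable-cell counts keyed by formulation id;
* checkpoint JSON — full engine state, so the loop survives arbitrarily
  long gaps between generations.

Every output embeds a schema tag, the seed and a config hash, so a run is
reconstructable from its artifacts.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import posthoc, similarity
from .engine import EngineConfig, EvaluationLibrary, HDDERun, run as engine_run
from .landscapes import BenchmarkLandscape, SyntheticCellLandscape
from .space import FactorSpace, load_space, total_combinations

SCHEMA = "hdde-v1"

__all__ = ["RunConfig", "simulate", "propose", "ingest", "analyze", "status"]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    space: FactorSpace
    engine: EngineConfig
    evaluator: str = "benchmark"            # benchmark | synthetic | external
    evaluator_params: dict = field(default_factory=dict)
    outdir: str = "."

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))
        space_entry = doc["space"]
        if isinstance(space_entry, str):
            space = load_space(os.path.join(base, space_entry))
        else:
            from .space import Factor
            space = FactorSpace(tuple(
                Factor(name=f["name"], dose_levels=tuple(f["dose_levels"]),
                       unit=f.get("unit", ""))
                for f in space_entry["factors"]))
        engine = EngineConfig(**doc.get("engine", {}))
        return cls(space=space, engine=engine,
                   evaluator=doc.get("evaluator", "benchmark"),
                   evaluator_params=doc.get("evaluator_params", {}),
                   outdir=doc.get("outdir", base))

    def config_hash(self) -> str:
        doc = {
            "engine": self.engine.__dict__,
            "evaluator": self.evaluator,
            "evaluator_params": self.evaluator_params,
            "space": [[f.name, list(f.dose_levels)] for f in self.space.factors],
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]

    def make_evaluator(self):
        p = dict(self.evaluator_params)
        if self.evaluator == "benchmark":
            return BenchmarkLandscape(self.space, **p)
        if self.evaluator == "synthetic":
            if "coefficients" in p:
                path, seed = p["coefficients"], p.get("seed", 0)
                return SyntheticCellLandscape.from_csv(path, self.space, seed=seed)
            return SyntheticCellLandscape.random(self.space, seed=p.get("seed", 0))
        raise ValueError(f"evaluator {self.evaluator!r} has no in silico model "
                         "(use propose/ingest for external mode)")


def _meta_line(config: RunConfig, **extra) -> str:
    fields = {"schema": SCHEMA, "seed": config.engine.seed,
              "config_sha": config.config_hash(), **extra}
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items())


def _write_csv(df: pd.DataFrame, path, meta: str) -> None:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(meta + "\n" + buf.getvalue())


def _read_csv(path) -> pd.DataFrame:
    # round_trip parser: response values must survive the CSV hand-off bit-exactly
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _levels_str(levels) -> str:
    return "-".join(str(int(v)) for v in levels)


def _parse_levels(s: str) -> tuple[int, ...]:
    return tuple(int(v) for v in str(s).split("-"))


# ---------------------------------------------------------------------------
# Lab-in-the-loop: propose / ingest


def propose(config: RunConfig, checkpoint_path, recipe_path) -> pd.DataFrame:
    """Write the recipe CSV for the next generation.

    Creates a fresh run when no checkpoint exists.  Idempotent: re-running
    against the same checkpoint reproduces the identical file, because the
    pending trial batch is part of the engine state.
    """
    if os.path.exists(checkpoint_path):
        state = HDDERun.load_checkpoint(checkpoint_path)
    else:
        state = HDDERun(config.space, config.engine)
    batch = state.propose()
    rows = []
    for k, levels in enumerate(batch.formulations):
        fid = f"G{batch.generation:02d}_{k + 1:03d}"
        row = {"formulation_id": fid, "generation": batch.generation,
               "levels": _levels_str(levels)}
        for fac, lev in zip(config.space.factors, levels):
            row[f"{fac.name}_level"] = lev + 1          # 1-based for humans
            row[f"{fac.name}_conc"] = fac.dose_levels[lev]
        rows.append(row)
    for r in range(batch.replicates):
        rows.append({"formulation_id": "PC", "generation": batch.generation,
                     "levels": ""})
    df = pd.DataFrame(rows)
    _write_csv(df, recipe_path, _meta_line(config, generation=batch.generation))
    state.save_checkpoint(checkpoint_path)
    return df


def ingest(config: RunConfig, checkpoint_path, responses_path) -> HDDERun:
    """Feed a responses CSV back into the loop and close the generation."""
    state = HDDERun.load_checkpoint(checkpoint_path)
    df = _read_csv(responses_path)
    required = {"formulation_id", "generation", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"responses CSV must have columns {sorted(required)}")
    gen = int(df["generation"].iloc[0])
    if state.finished or gen != state.generation + 1:
        raise ValueError(
            f"generation {gen} already closed (engine at generation "
            f"{state.generation}); re-ingestion rejected")
    batch = state.propose()
    ids = {f"G{batch.generation:02d}_{k + 1:03d}": levels
           for k, levels in enumerate(batch.formulations)}
    responses: dict[tuple, list[float]] = {}
    censored: dict[tuple, list[bool]] = {}
    pc: list[float] = []
    unknown = []
    for _, row in df.iterrows():
        fid = row["formulation_id"]
        try:
            val = float(row["response"])
        except (TypeError, ValueError):
            raise ValueError(f"malformed numeric response for id {fid!r}: "
                             f"{row['response']!r}")
        if fid == "PC":
            pc.append(val)
            continue
        if fid not in ids:
            unknown.append(fid)
            continue
        lv = ids[fid]
        responses.setdefault(lv, []).append(val)
        censored.setdefault(lv, []).append(bool(row.get("censored", False)))
    if unknown:
        raise KeyError(f"responses for unknown formulation ids: {sorted(set(unknown))}")
    missing = [fid for fid, lv in ids.items() if lv not in responses]
    if missing:
        raise KeyError(f"no responses for proposed formulations: {missing}")
    short = [fid for fid, lv in ids.items()
             if len(responses[lv]) < state.config.replicates]
    if short:
        raise ValueError(f"fewer than {state.config.replicates} replicates for: {short}")
    if not pc:
        raise ValueError("no positive-control (PC) responses in file")
    state.ingest(responses, pc=pc, censored=censored)
    state.save_checkpoint(checkpoint_path)
    return state


def status(checkpoint_path) -> dict:
    state = HDDERun.load_checkpoint(checkpoint_path)
    best = state.cset.best(state.library) if state.cset.members else (None, float("nan"))
    return {
        "generation": state.generation,
        "finished": state.finished,
        "termination_reason": state.termination_reason,
        "unique_count": state.library.unique_count,
        "best_score": best[1],
        "best_formulation": list(best[0]) if best[0] else None,
        "F": state.F,
        "CR": state.CR,
    }


# ---------------------------------------------------------------------------
# In silico simulation


def simulate(config: RunConfig) -> dict:
    """Run a whole campaign against the configured in silico evaluator and
    write library, candidate-set, populations, trace and summary artifacts."""
    evaluator = config.make_evaluator()
    state = engine_run(config.space, config.engine, evaluator)
    os.makedirs(config.outdir, exist_ok=True)
    meta = _meta_line(config)

    write_library_csv(state.library, os.path.join(config.outdir, "library.csv"), meta)

    cand_rows = [{"formulation_id": _levels_str(m), "levels": _levels_str(m),
                  "score": state.library.score(m)} for m in state.cset.members]
    cand = pd.DataFrame(cand_rows).sort_values("score", ascending=False)
    _write_csv(cand, os.path.join(config.outdir, "candidates.csv"), meta)

    trace = pd.DataFrame([r.__dict__ for r in state.trace])
    _write_csv(trace, os.path.join(config.outdir, "trace.csv"), meta)

    pop_rows = [{"generation": g + 1, "slot": i, "levels": _levels_str(f)}
                for g, pop in enumerate(state.population_history)
                for i, f in enumerate(pop)]
    _write_csv(pd.DataFrame(pop_rows),
               os.path.join(config.outdir, "population.csv"), meta)

    state.save_checkpoint(os.path.join(config.outdir, "checkpoint.json"))

    frac = state.library.unique_count / total_combinations(config.space) * 100.0
    summary = {
        "schema": SCHEMA,
        "seed": config.engine.seed,
        "config_sha": config.config_hash(),
        "generations": state.generation,
        "termination_reason": state.termination_reason,
        "unique_count": state.library.unique_count,
        "total_combinations": total_combinations(config.space),
        "search_space_fraction_percent": frac,
        "best_score": state.cset.best(state.library)[1],
    }
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def write_library_csv(library: EvaluationLibrary, path, meta: str = "# " + SCHEMA) -> None:
    rows = []
    for levels, entry in library.items():
        fid = _levels_str(levels)
        for r, (v, g, c) in enumerate(zip(entry.values, entry.generations,
                                          entry.censored)):
            rows.append({"formulation_id": fid, "levels": fid, "generation": g,
                         "replicate": r + 1, "response": v, "censored": c,
                         "is_control": False})
    for r, (v, g) in enumerate(zip(library._pc.values, library._pc.generations)):
        rows.append({"formulation_id": "PC", "levels": "", "generation": g,
                     "replicate": r + 1, "response": v, "censored": False,
                     "is_control": True})
    _write_csv(pd.DataFrame(rows), path, meta)


def read_library_csv(path) -> EvaluationLibrary:
    df = _read_csv(path)
    lib = EvaluationLibrary()
    for fid, grp in df[~df["is_control"]].groupby("formulation_id", sort=False):
        lib.add(_parse_levels(grp["levels"].iloc[0]),
                grp["response"].tolist(),
                int(grp["generation"].iloc[0]),
                grp["censored"].tolist())
        entry = lib.get(_parse_levels(grp["levels"].iloc[0]))
        entry.generations = [int(g) for g in grp["generation"]]
    pc = df[df["is_control"]]
    for g, grp in pc.groupby("generation"):
        lib.add_pc(grp["response"].tolist(), int(g))
    return lib


# ---------------------------------------------------------------------------
# Post hoc analysis driver


def analyze(library_path, space: FactorSpace, outdir,
            population_path=None, seed: int = 0, top_n: int = 20) -> dict:
    """Quadratic-model and similarity outputs from a library CSV.

    Writes coefficients.csv (term, estimate, FDR logworth, FDR p), a
    volcano-ready CSV, Hamming/Levenshtein distance matrices over the
    ``top_n`` highest-scoring formulations, and (when a population trace is
    supplied) a consecutive-generation similarity summary.  Outputs embed
    the input library's checksum.
    """
    os.makedirs(outdir, exist_ok=True)
    with open(library_path, "rb") as fh:
        lib_sha = hashlib.sha256(fh.read()).hexdigest()[:12]
    meta = f"# schema={SCHEMA} library_sha={lib_sha} seed={seed} log=natural"
    library = read_library_csv(library_path)

    design = posthoc.build_design(library, space, rng=np.random.default_rng(seed))
    result = posthoc.fit_quadratic(design)
    coeffs = result.table[["term", "estimate", "logworth", "p_fdr"]]
    _write_csv(coeffs, os.path.join(outdir, "coefficients.csv"), meta)
    _write_csv(posthoc.volcano_table(result),
               os.path.join(outdir, "volcano.csv"), meta)

    scored = sorted(((library.score(lv), lv) for lv, _ in library.items()),
                    reverse=True)[:top_n]
    tops = [lv for _, lv in scored]
    labels = [_levels_str(lv) for lv in tops]
    summaries = {}
    for metric in ("hamming", "levenshtein_eq"):
        dm = similarity.pairwise_matrix(tops, metric=metric, labels=labels)
        _write_csv(dm.to_long(), os.path.join(outdir, f"distance_{metric}.csv"), meta)
        summaries[metric] = {"mean": dm.mean_off_diagonal,
                             "median": dm.median_off_diagonal}

    if population_path is not None:
        pops = _read_csv(population_path)
        sim_rows = []
        by_gen = {g: [_parse_levels(s) for s in grp.sort_values("slot")["levels"]]
                  for g, grp in pops.groupby("generation")}
        gens = sorted(by_gen)
        for a, b in zip(gens, gens[1:]):
            for metric in ("hamming", "levenshtein_eq"):
                s = similarity.generation_similarity(by_gen[a], by_gen[b], metric)
                sim_rows.append({"from_generation": a, "to_generation": b,
                                 "metric": metric,
                                 "mean_distance": s["mean_distance"],
                                 "carried_fraction": s["carried_fraction"]})
        _write_csv(pd.DataFrame(sim_rows),
                   os.path.join(outdir, "generation_similarity.csv"), meta)

    return {"library_sha": lib_sha, "n_terms": len(result.table),
            "dropped_terms": result.dropped_terms, "similarity": summaries}
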