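"""CSV hand-off, checkpointed lab-in-the-loop drivers, and the CLI."""

import json
import math
import os

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from hdde.cli import main as cli_main
from hdde.engine import EngineConfig, HDDERun, run as engine_run
from hdde.landscapes import SyntheticCellLandscape
from hdde.runio import (
    RunConfig,
    analyze,
    ingest,
    propose,
    read_library_csv,
    simulate,
    status,
    write_library_csv,
)
from hdde.space import Factor, FactorSpace, save_space, total_combinations


def small_space():
    return FactorSpace((
        Factor("glc", (0.5, 2.0, 8.0)),
        Factor("gln", (0.1, 0.4, 1.6)),
        Factor("fe", (1.0, 3.0, 9.0, 27.0)),
    ))


def make_config(tmp_path, seed=3, max_generations=4, evaluator="synthetic",
                **engine_kw):
    engine_kw.setdefault("early_stop", False)
    return RunConfig(
        space=small_space(),
        engine=EngineConfig(seed=seed, max_generations=max_generations,
                            **engine_kw),
        evaluator=evaluator,
        evaluator_params={"seed": 11},
        outdir=str(tmp_path / "out"),
    )


def config_yaml(tmp_path, seed=3, max_generations=4):
    doc = {
        "space": {"factors": [
            {"name": f.name, "dose_levels": list(f.dose_levels)}
            for f in small_space().factors]},
        "engine": {"seed": seed, "max_generations": max_generations,
                   "early_stop": False},
        "evaluator": "synthetic",
        "evaluator_params": {"seed": 11},
        "outdir": str(tmp_path / "out"),
    }
    p = tmp_path / "config.yaml"
    p.write_text(yaml.safe_dump(doc))
    return p


def run_lab_loop(config, tmp_path, land):
    """Drive propose/ingest with a simulated bench until termination."""
    ck = str(tmp_path / "ck.json")
    gen = 0
    while True:
        gen += 1
        recipe = str(tmp_path / f"recipe_g{gen}.csv")
        df = propose(config, ck, recipe)
        responses = _assay(df, land, config)
        rp = str(tmp_path / f"responses_g{gen}.csv")
        responses.to_csv(rp, index=False)
        state = ingest(config, ck, rp)
        if state.finished:
            return state, ck


def _assay(recipe_df, land, config):
    """Simulated bench: evaluate each recipe row and return a responses CSV."""
    reps = config.engine.replicates
    rows = []
    gen = int(recipe_df["generation"].iloc[0])
    formulations = [tuple(int(v) for v in s.split("-"))
                    for s in recipe_df.loc[recipe_df["formulation_id"] != "PC",
                                           "levels"]]
    resp, cens = land.evaluate_censored(formulations, gen, reps)
    for fid, lv in zip(recipe_df.loc[recipe_df["formulation_id"] != "PC",
                                     "formulation_id"], formulations):
        for v, c in zip(resp[lv], cens[lv]):
            rows.append({"formulation_id": fid, "generation": gen,
                         "response": v, "censored": c})
    for v in land.pc(gen, reps):
        rows.append({"formulation_id": "PC", "generation": gen,
                     "response": v, "censored": False})
    return pd.DataFrame(rows)


class TestSimulate:
    def test_artifacts_written_and_summary_consistent(self, tmp_path):
        cfg = make_config(tmp_path)
        summary = simulate(cfg)
        out = tmp_path / "out"
        for name in ("library.csv", "candidates.csv", "trace.csv",
                     "population.csv", "checkpoint.json", "summary.json"):
            assert (out / name).exists()
        lib = read_library_csv(out / "library.csv")
        assert lib.unique_count == summary["unique_count"]
        assert summary["total_combinations"] == total_combinations(cfg.space)
        assert summary["search_space_fraction_percent"] == pytest.approx(
            summary["unique_count"] / summary["total_combinations"] * 100)

    def test_identical_configs_reproduce_identical_artifacts(self, tmp_path):
        a = make_config(tmp_path / "a")
        b = make_config(tmp_path / "b")
        sa, sb = simulate(a), simulate(b)
        assert sa == sb
        for name in ("library.csv", "trace.csv", "population.csv"):
            fa = (tmp_path / "a" / "out" / name).read_text()
            fb = (tmp_path / "b" / "out" / name).read_text()
            assert fa == fb

    def test_library_csv_roundtrip_is_bit_exact(self, tmp_path):
        cfg = make_config(tmp_path)
        simulate(cfg)
        p = tmp_path / "out" / "library.csv"
        lib = read_library_csv(p)
        p2 = tmp_path / "copy.csv"
        write_library_csv(lib, p2)
        assert read_library_csv(p2).to_dict() == lib.to_dict()


class TestProposeIngest:
    def test_propose_is_idempotent_byte_for_byte(self, tmp_path):
        cfg = make_config(tmp_path)
        ck = str(tmp_path / "ck.json")
        r1, r2 = str(tmp_path / "r1.csv"), str(tmp_path / "r2.csv")
        propose(cfg, ck, r1)
        propose(cfg, ck, r2)
        assert open(r1).read() == open(r2).read()

    def test_recipe_contains_pc_rows_and_one_based_levels(self, tmp_path):
        cfg = make_config(tmp_path)
        df = propose(cfg, str(tmp_path / "ck.json"), str(tmp_path / "r.csv"))
        assert (df["formulation_id"] == "PC").sum() == cfg.engine.replicates
        body = df[df["formulation_id"] != "PC"]
        assert body["glc_level"].between(1, 3).all()
        # concentration column matches the dose grid lookup
        for _, row in body.iterrows():
            lv = int(row["glc_level"]) - 1
            assert row["glc_conc"] == cfg.space.factors[0].dose_levels[lv]

    def test_lab_loop_reproduces_in_silico_simulation_state(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        state, ck = run_lab_loop(cfg, tmp_path, land)

        ref = engine_run(cfg.space, cfg.engine,
                         SyntheticCellLandscape.random(cfg.space, seed=11))
        assert state.library.to_dict() == ref.library.to_dict()
        assert state.cset.members == ref.cset.members
        assert [r.__dict__ for r in state.trace] == [r.__dict__ for r in ref.trace]
        assert state.population_history == ref.population_history

    def test_double_ingestion_rejected(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        ck = str(tmp_path / "ck.json")
        df = propose(cfg, ck, str(tmp_path / "r.csv"))
        resp = _assay(df, land, cfg)
        rp = str(tmp_path / "resp.csv")
        resp.to_csv(rp, index=False)
        ingest(cfg, ck, rp)
        with pytest.raises(ValueError, match="already closed"):
            ingest(cfg, ck, rp)

    def test_unknown_formulation_id_rejected(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        ck = str(tmp_path / "ck.json")
        df = propose(cfg, ck, str(tmp_path / "r.csv"))
        resp = _assay(df, land, cfg)
        resp.loc[0, "formulation_id"] = "G01_999"
        rp = str(tmp_path / "resp.csv")
        resp.to_csv(rp, index=False)
        with pytest.raises(KeyError, match="unknown"):
            ingest(cfg, ck, rp)

    def test_missing_replicates_rejected(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        ck = str(tmp_path / "ck.json")
        df = propose(cfg, ck, str(tmp_path / "r.csv"))
        resp = _assay(df, land, cfg)
        fid = resp.loc[resp["formulation_id"] != "PC", "formulation_id"].iloc[0]
        resp = resp.drop(resp[resp["formulation_id"] == fid].index[:1])
        rp = str(tmp_path / "resp.csv")
        resp.to_csv(rp, index=False)
        with pytest.raises(ValueError, match="replicates"):
            ingest(cfg, ck, rp)

    def test_missing_pc_rejected(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        ck = str(tmp_path / "ck.json")
        df = propose(cfg, ck, str(tmp_path / "r.csv"))
        resp = _assay(df, land, cfg)
        resp = resp[resp["formulation_id"] != "PC"]
        rp = str(tmp_path / "resp.csv")
        resp.to_csv(rp, index=False)
        with pytest.raises(ValueError, match="positive-control"):
            ingest(cfg, ck, rp)

    def test_status_reports_progress(self, tmp_path):
        cfg = make_config(tmp_path)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        state, ck = run_lab_loop(cfg, tmp_path, land)
        s = status(ck)
        assert s["finished"] is True
        assert s["generation"] == state.generation
        assert s["unique_count"] == state.library.unique_count
        assert s["best_score"] == pytest.approx(state.cset.best(state.library)[1])


class TestAnalyze:
    def test_outputs_and_sigma_zero_coefficients(self, tmp_path):
        cfg = make_config(tmp_path, seed=4)
        land = SyntheticCellLandscape.random(cfg.space, seed=11, sigma=0.0)
        land.block_offsets = {}
        st = engine_run(cfg.space, cfg.engine, land)
        lib_path = tmp_path / "library.csv"
        write_library_csv(st.library, lib_path)
        out = analyze(lib_path, cfg.space, tmp_path / "analysis")
        for name in ("coefficients.csv", "volcano.csv",
                     "distance_hamming.csv", "distance_levenshtein_eq.csv"):
            assert (tmp_path / "analysis" / name).exists()
        coeffs = pd.read_csv(tmp_path / "analysis" / "coefficients.csv",
                             comment="#").set_index("term")
        # exact recovery is only claimed for a full-rank design; assert the
        # precondition so a collinear visit pattern fails loudly
        assert out["dropped_terms"] == []
        names = [f.name for f in cfg.space.factors]
        for j, n in enumerate(names):
            assert coeffs.loc[n, "estimate"] == pytest.approx(
                land.mains[j], abs=1e-8)

    def test_similarity_summary_from_population_trace(self, tmp_path):
        cfg = make_config(tmp_path)
        simulate(cfg)
        out_dir = tmp_path / "out"
        res = analyze(out_dir / "library.csv", cfg.space, tmp_path / "an",
                      population_path=out_dir / "population.csv")
        sim = pd.read_csv(tmp_path / "an" / "generation_similarity.csv",
                          comment="#")
        assert set(sim["metric"]) == {"hamming", "levenshtein_eq"}
        assert sim["carried_fraction"].between(0, 1).all()
        assert res["similarity"]["hamming"]["mean"] >= 0

    def test_single_generation_library_refused(self, tmp_path):
        cfg = make_config(tmp_path, max_generations=1)
        st = engine_run(cfg.space, cfg.engine, cfg.make_evaluator())
        lib_path = tmp_path / "library.csv"
        write_library_csv(st.library, lib_path)
        from hdde.posthoc import AnalysisError
        with pytest.raises(AnalysisError):
            analyze(lib_path, cfg.space, tmp_path / "an")


class TestRunConfig:
    def test_yaml_loading_inline_space(self, tmp_path):
        p = config_yaml(tmp_path)
        cfg = RunConfig.load(p)
        assert cfg.space.D == 3
        assert cfg.engine.seed == 3
        assert cfg.evaluator == "synthetic"

    def test_yaml_loading_space_file_reference(self, tmp_path):
        sp_path = tmp_path / "space.yaml"
        save_space(small_space(), sp_path)
        doc = {"space": "space.yaml", "engine": {"seed": 1}}
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(doc))
        cfg = RunConfig.load(p)
        assert cfg.space == small_space()

    def test_config_hash_sensitive_to_engine_changes(self, tmp_path):
        a = make_config(tmp_path, seed=3)
        b = make_config(tmp_path, seed=4)
        assert a.config_hash() != b.config_hash()
        assert a.config_hash() == make_config(tmp_path, seed=3).config_hash()

    def test_external_evaluator_has_no_model(self, tmp_path):
        cfg = make_config(tmp_path, evaluator="external")
        with pytest.raises(ValueError):
            cfg.make_evaluator()


class TestCli:
    def test_simulate_and_status(self, tmp_path):
        p = config_yaml(tmp_path)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", str(p)])
        assert res.exit_code == 0, res.output
        summary = json.loads(res.output)
        assert summary["unique_count"] > 0
        res2 = runner.invoke(cli_main, [
            "status", "--checkpoint", str(tmp_path / "out" / "checkpoint.json")])
        assert res2.exit_code == 0, res2.output
        assert json.loads(res2.output)["finished"] is True

    def test_init_then_ingest_round(self, tmp_path):
        p = config_yaml(tmp_path)
        ck = tmp_path / "ck.json"
        recipe = tmp_path / "recipe.csv"
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "init", "--config", str(p), "--checkpoint", str(ck),
            "--out", str(recipe)])
        assert res.exit_code == 0, res.output
        cfg = RunConfig.load(p)
        land = SyntheticCellLandscape.random(cfg.space, seed=11)
        df = pd.read_csv(recipe, comment="#")
        resp = _assay(df, land, cfg)
        rp = tmp_path / "resp.csv"
        resp.to_csv(rp, index=False)
        res2 = runner.invoke(cli_main, [
            "ingest", "--config", str(p), "--checkpoint", str(ck),
            "--responses", str(rp)])
        assert res2.exit_code == 0, res2.output
        assert json.loads(res2.output.splitlines()[0])["generation"] == 1
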