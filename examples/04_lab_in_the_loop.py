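"""Lab-in-the-loop workflow: recipe CSV out, responses CSV in.

This is the exchange a wet lab would run with the `hdde` CLI — here the
"bench" is simulated in-process so the example is self-contained.  Each
cycle is:

  1. propose  -> recipe CSV (dose levels + concentrations, PC rows)
                 and a JSON checkpoint holding the full engine state;
  2. assay    -> the lab fills a responses CSV (replicate counts);
  3. ingest   -> the engine closes the generation and updates the
                 checkpoint; the loop survives any gap between steps.

Equivalent shell session:

  hdde init    --config run.yaml --checkpoint ck.json --out recipe_g1.csv
  # ... culture, count cells, fill responses_g1.csv ...
  hdde ingest  --config run.yaml --checkpoint ck.json --responses responses_g1.csv
  hdde propose --config run.yaml --checkpoint ck.json --out recipe_g2.csv
  hdde status  --checkpoint ck.json

Run:  python examples/04_lab_in_the_loop.py
"""

import tempfile
from pathlib import Path

import pandas as pd

from hdde import EngineConfig, SyntheticCellLandscape
from hdde.runio import RunConfig, ingest, propose, status
from hdde.space import Factor, FactorSpace

space = FactorSpace((
    Factor("SCF", (5.0, 15.0, 45.0), unit="ng/mL"),
    Factor("IL3", (2.0, 6.0, 18.0), unit="ng/mL"),
    Factor("transferrin", (2.5, 10.0, 40.0), unit="ug/mL"),
    Factor("selenite", (5.0, 20.0, 80.0), unit="nM"),
))
config = RunConfig(space=space,
                   engine=EngineConfig(seed=7, max_generations=4,
                                       early_stop=False),
                   evaluator="external")
bench = SyntheticCellLandscape.random(space, seed=30)   # stand-in wet lab

workdir = Path(tempfile.mkdtemp())
checkpoint = workdir / "checkpoint.json"

for cycle in range(1, config.engine.max_generations + 1):
    recipe_path = workdir / f"recipe_g{cycle}.csv"
    recipe = propose(config, checkpoint, recipe_path)
    n = (recipe["formulation_id"] != "PC").sum()
    print(f"cycle {cycle}: proposed {n} formulations -> {recipe_path.name}")

    # --- simulated bench work: assay every recipe row ---------------------
    rows = []
    plates = recipe[recipe["formulation_id"] != "PC"]
    levels = [tuple(int(v) for v in s.split("-")) for s in plates["levels"]]
    resp, cens = bench.evaluate_censored(levels, cycle,
                                         config.engine.replicates)
    for fid, lv in zip(plates["formulation_id"], levels):
        for v, c in zip(resp[lv], cens[lv]):
            rows.append({"formulation_id": fid, "generation": cycle,
                         "response": v, "censored": c})
    for v in bench.pc(cycle, config.engine.replicates):
        rows.append({"formulation_id": "PC", "generation": cycle,
                     "response": v, "censored": False})
    responses_path = workdir / f"responses_g{cycle}.csv"
    pd.DataFrame(rows).to_csv(responses_path, index=False)
    # ----------------------------------------------------------------------

    state = ingest(config, checkpoint, responses_path)
    print(f"         ingested -> generation {state.generation} closed, "
          f"best score {state.cset.best(state.library)[1]:.3f}")
    if state.finished:
        break

print()
print("final checkpoint status:", status(checkpoint))
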