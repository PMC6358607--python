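# hdde — closed-loop differential evolution for media formulation search

`hdde` finds high-performing cell-culture media formulations in discrete
dose-combination spaces far too large to screen: 15 factors at 6 dose
levels each is ~4.7 × 10¹¹ combinations, while a realistic campaign can
afford a few hundred assays. It implements a high-dimensional variant of
differential evolution (HD-DE) designed for exactly this setting —
noisy, expensive, batched biological readouts — and the surrounding
machinery of a closed experimental loop:

- **noise-aware selection** — a trial formulation replaces its incumbent
  only when its replicate median is higher *and* a one-sided exact
  Wilcoxon rank-sum test rejects at α = 0.10; ties keep the incumbent,
  so measurement noise cannot silently churn the population;
- **a persistent, deduplicating evaluation library** — no formulation is
  ever assayed twice; every score is normalized to the generation's
  positive control;
- **a candidate solution set with competition-against-best and
  clearing** — the best formulations encountered anywhere are kept,
  pruned to within 10% of the leader once the search contracts, and
  cleared members are replaced by one-dose-step perturbations of
  surviving roots;
- **an adaptive F/CR schedule** — mutation weight drops 1.0 → 0.5 when
  the best score plateaus, crossover 0.5 → 0.25 once the population
  stabilizes, shifting from exploration to refinement;
- **a propose/ingest state machine** — each generation is a recipe CSV
  out and a responses CSV in, with the full engine state in a JSON
  checkpoint, so the same engine drives in silico simulations and a
  wet lab with days between generations.

After a campaign, the post hoc module pools every assayed formulation
into a quadratic response-surface model (mains, squares, two-factor
crossproducts, generation-block contrasts) with left-censored responses
imputed by censored-normal maximum likelihood and effects screened by
Benjamini–Hochberg FDR logworths.

## Worked example

```python
from hdde import EngineConfig, SyntheticCellLandscape, run
from hdde.space import example_space

space = example_space(D=15, n_levels=6)            # 6^15 combinations
landscape = SyntheticCellLandscape.random(space, seed=0)
state = run(space, EngineConfig(seed=0), landscape)
```

Running `python examples/01_synthetic_campaign.py` (which adds trace
printing) gives:

```
 gen    best    mean  improved  carried    F    CR  uniques
   1   0.146   0.057         0        0  1.0  0.50       45
   2   0.380   0.100        18       27  1.0  0.50       90
   3   0.400   0.124        12       33  1.0  0.50      135
   4   0.398   0.154        14       31  1.0  0.50      180
   5   0.466   0.176        11       34  1.0  0.50      225
   6   0.473   0.198         6       39  1.0  0.50      270
   7   0.480   0.217         6        2  1.0  0.50      315
   8   0.557   0.429         4       39  0.5  0.25      381
   9   0.623   0.434         1       38  0.5  0.25      422
  10   0.623   0.473         2       43  0.5  0.25      468
  11   0.675   0.480         3       42  0.5  0.25      511

terminated: population_converged after 11 generations
best formulation (0-based dose levels): (0, 0, 5, 3, 5, 0, 5, 3, 2, 4, 0, 5, 4, 3, 5)
best score vs positive control:          0.675
unique formulations assayed:             511
fraction of the search space:            1.09e-07 %
```

The engine converged after assaying 511 of 470 billion combinations.
The low `carried` value at generation 7 is the clearing step firing:
pruned candidate-set members are re-injected as perturbed roots,
counted as population turnover.

The other examples cover the benchmark study against classic DE and
random search (`02`), the post hoc quadratic screen (`03`), and the
CSV-based lab-in-the-loop workflow (`04`).

## Command line

A thin `hdde` CLI wraps the library for bench use:

```sh
hdde init     --config run.yaml --checkpoint ck.json --out recipe_g1.csv
hdde ingest   --config run.yaml --checkpoint ck.json --responses responses_g1.csv
hdde propose  --config run.yaml --checkpoint ck.json --out recipe_g2.csv
hdde status   --checkpoint ck.json
hdde simulate --config run.yaml                      # full in silico campaign
hdde analyze  --library out/library.csv --space space.yaml --outdir analysis/
```

Recipe CSVs carry 1-based dose levels next to real concentrations plus
positive-control rows; all artifacts embed a schema tag, seed, and
config hash.

## Layout

```
src/hdde/        space, engine, landscapes, similarity, posthoc,
                 baselines, runio, cli
tests/           unit + property + acceptance tests
examples/        narrative scripts (start here)
docs/methods.md  model details, parameter rationale, limitations
scripts/         acceptance.py
```
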