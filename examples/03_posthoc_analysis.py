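"""Post hoc response-surface analysis of a finished campaign.

Runs a small campaign, pools every assayed formulation from generation 2
onward, fits the full quadratic model (mains + squares + two-factor
crossproducts + generation-block contrasts) to the log responses, and
prints a volcano-style effect screen with FDR logworths, followed by a
dose-distance profile of the top candidates.

Run:  python examples/03_posthoc_analysis.py
"""

import numpy as np

from hdde import EngineConfig, SyntheticCellLandscape, run
from hdde.posthoc import build_design, fit_quadratic, volcano_table
from hdde.similarity import pairwise_matrix
from hdde.space import mixed_level_space

space = mixed_level_space([4, 4, 4, 3, 3, 3])
landscape = SyntheticCellLandscape.random(space, seed=2)
state = run(space, EngineConfig(seed=2, max_generations=8, early_stop=False),
            landscape)

design = build_design(state.library, space, rng=np.random.default_rng(0))
result = fit_quadratic(design)
volcano = volcano_table(result)

print(f"rows in design: {result.n_obs}   pruned collinear terms: "
      f"{result.dropped_terms or 'none'}")
print()
print("top effects by FDR logworth (-log10 adjusted p):")
print(volcano.head(10).to_string(index=False,
                                 float_format=lambda v: f"{v:8.3f}"))

scored = sorted(((state.library.score(f), f) for f, _ in state.library.items()),
                reverse=True)[:10]
dm = pairwise_matrix([f for _, f in scored], metric="levenshtein_eq")
print()
print("top-10 candidates, mean pairwise dose distance "
      f"(Levenshtein-equivalent): {dm.mean_off_diagonal:.2f}")
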