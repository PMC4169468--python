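"""Is a trait relationship phylogenetic or strain-specific?

Simulates 100 strains on a coalescent tree where only the phylogenetic
component links the two traits, fits the two-component model, and compares
the regression slope of response on predictor between components: an HPD
of (b_phylo - b_strain) excluding zero attributes the link to ancestry.
Takes a minute or two.
"""

import numpy as np
import pandas as pd

from symbiocomp.comparative import ModelSpec, component_regression_compare, fit_multiresponse
from symbiocomp.phylo import shared_ancestry_matrix
from symbiocomp.simulate import simulate_strain_effects, simulate_tree

tree = simulate_tree(100, seed=11)
V_p = np.array([[1.0, 0.8], [0.8, 1.0]])   # the link lives here
V_s = np.eye(2)                             # no strain-level covariance
effects, _ = simulate_strain_effects(tree, V_s, V_p, seed=12,
                                     trait_names=["survival", "density"])
rng = np.random.default_rng(13)
rows = [(s, t, effects.loc[s, t] + rng.normal(0, 0.4))
        for s in effects.index for t in effects.columns for _ in range(6)]
table = pd.DataFrame(rows, columns=["strain", "trait", "value"])

spec = ModelSpec(traits=("survival", "density"), include_strain_effect=True,
                 include_phylo_effect=True, A=shared_ancestry_matrix(tree),
                 prior="inverse-wishart",
                 iterations=15_000, burn_in=3_000, thin=6, seed=14)
draws = fit_multiresponse(table, spec)
out = component_regression_compare(draws, "survival", "density")
print(f"b_phylo = {out['b_phylo_mean']:.2f}, b_strain = {out['b_strain_mean']:.2f}")
print(f"difference: {out['mean']:.2f}, 95% HPD "
      f"[{out['hpd_lower']:.2f}, {out['hpd_upper']:.2f}]")
print("HPD excluding 0 => the survival-density regression is carried by the"
      if out["significant"] else "HPD includes 0 => no component attribution;",
      "phylogenetic component, as simulated." if out["significant"] else "")
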