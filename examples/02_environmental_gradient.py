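"""Estimate the environmental gradient from contemporary-group effects.

Applies the record filters (minimum CG size, 3.5-SD outliers), estimates
each CG's effect by fixed-effects BLUE, and standardizes the estimates
into the gradient θ̂ used by the reaction-norm model.
"""

import numpy as np

import gxenorm as gx

cfg = gx.SimConfig(n_founders=200, n_generations=3, litter_size_mean=6,
                   n_matings_per_gen=60, n_cg=24, n_parities=2, seed=2,
                   n_auto_snps=10, n_x_snps=0)
params = gx.TrueParameters(blocks={"a": np.array([[1.0, 0.0], [0.0, 0.1]])},
                           sigma2_e=2.0, mean=12.0, sex_effect=0.3, b=1.0)
ped = gx.simulate_pedigree(cfg)
pheno, truth = gx.simulate_phenotypes(ped, params, cfg)

filtered, log = gx.apply_record_filters(pheno, min_cg=10, sd_cut=3.5)
print(f"records in/out         : {log['records_in']} / {log['records_out']}"
      f" (small-CG {log['dropped_small_cg']},"
      f" outliers {log['dropped_outliers']})")

spec = gx.ModelSpec(factors=["sex"])
gradient = gx.build_gradient(filtered, spec)
theta = gradient.theta
print(f"retained CGs           : {len(theta)}  "
      f"(mean {theta.mean():+.1e}, SD {theta.std(ddof=1):.6f})")
print(f"gradient range         : {theta.min():+.2f} .. {theta.max():+.2f}")
r = np.corrcoef(theta.to_numpy(),
                truth.theta.reindex(theta.index).to_numpy())[0, 1]
print(f"corr(θ̂, true gradient) : {r:.3f}")
print("θ̂ is standardized (mean 0, SD 1); its high correlation with the "
      "generative CG effects shows the BLUE step recovers the environment.")
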