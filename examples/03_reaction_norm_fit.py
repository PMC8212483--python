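"""Fit homogeneous and heteroscedastic reaction-norm models by AI-REML.

Simulates data with residual variance increasing along the gradient
(Var(e) = exp(d0 + d1 θ)), fits both residual structures with the
single-step machinery, and lets AIC choose.
"""

import numpy as np

import gxenorm as gx

cfg = gx.SimConfig(n_founders=80, n_generations=4, litter_size_mean=7,
                   n_matings_per_gen=22, n_cg=25, n_parities=2, seed=3,
                   n_auto_snps=200, n_x_snps=8, genotyping_fraction=0.5)
params = gx.TrueParameters(
    blocks={"a": np.array([[1.0, 0.25], [0.25, 0.18]])},
    sigma2_e=None, d0=np.log(2.0), d1=0.4, mean=12.0, sex_effect=0.3, b=0.8,
)
ped, geno, pheno, truth = gx.simulate_dataset(cfg, params)

spec = gx.ModelSpec(factors=["sex"], random_effects=("a",))
gradient = gx.build_gradient(pheno, spec)
keep = pheno.df["cg"].isin(set(gradient.theta.index))
pheno = gx.PhenotypeTable(pheno.df[keep], factors=["sex"])

# single-step: hybrid H⁻¹ from pedigree + blended genomic relationships
A, _ = gx.build_A(ped)
geno_qc, _ = gx.qc_genotypes(geno)
a22 = A.subset(geno_qc.ids)
G = gx.build_G(geno_qc, blend_a22=a22, blend_weight=0.05)
hinv = gx.build_Hinv(gx.build_A_inverse(ped),
                     gx.invert_relationship(a22, "A22inv"),
                     gx.invert_relationship(G, "Ginv"), geno_qc.ids)

fits = {}
for model in ("RNM1", "RNM2"):
    vc, fit = gx.reml_fit(pheno, gradient, spec, hinv, model=model)
    fits[model] = (vc, fit)
    B = vc.block("a")
    print(f"{model}: logL {fit.loglik:10.2f}  AIC {fit.aic:10.2f}  "
          f"var0 {B[0, 0]:.3f}  cov {B[0, 1]:.3f}  var1 {B[1, 1]:.3f}  "
          f"({fit.n_iterations} AI iterations)")

chosen = gx.choose_model(fits["RNM1"][1], fits["RNM2"][1])
vc, fit = fits[chosen]
print(f"AIC prefers            : {chosen} "
      f"(truth is heteroscedastic, d1 = 0.4; fitted d1 = {vc.d1:.3f})")
print(f"fixed regression b̂     : {fit.b:.3f} (truth 0.8)")
print("The heteroscedastic model wins on AIC and recovers the residual "
      "slope d1 well; at this deliberately small size the block estimates "
      "still carry visible sampling noise.")
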