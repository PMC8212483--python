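# Methods

This note records the statistical model the package implements, the
numerical choices behind the REML engine, what the synthetic-data
generator does and does not emulate, and the design decisions taken
where the published description of this type of analysis leaves the
details open.

## Model

For a phenotype of animal *j* recorded in contemporary group (CG) *i*:

    y_ij = x'_j β + b θ̂_i + Σ_n (n0_j + n1_j θ̂_i) + e_ij ,   n ∈ {a, pe, ce}

* **β** — systematic effects (factor levels, covariate powers) selected
  by backward elimination at P < 0.05 on partial F-tests; a quadratic
  covariate term must leave before its linear term is tested.
* **θ̂_i** — the environmental gradient: per-CG BLUE from a
  fixed-effects-only ordinary-least-squares model of all systematic
  effects plus CG under a sum-to-zero constraint, z-scored, with CGs
  beyond 3.5 SD removed and the remainder re-standardized to mean 0,
  SD 1. Records whose CG loses its gradient value are dropped before
  the mixed-model stage.
* **b** — an overall fixed regression of the phenotype on θ̂. By
  default the CG class effect is *replaced* by b·θ̂ inside the reaction
  norm (keeping CG as a class alongside the gradient it was estimated
  from would confound them exactly in balanced data); a
  `cg_as_class` switch restores the class effect for users who want
  both, because the published model descriptions are ambiguous on this
  point.
* **a, pe, ce** — additive-genetic, permanent-environment and
  birth-litter effects, each a (intercept, slope) pair. Covariances:
  H ⊗ B_a for the additive pairs, I ⊗ B_pe and I ⊗ B_ce for the others,
  each B a full 2×2 block. Which effects enter is selected by AIC over
  candidate subsets (the additive effect is never dropped).
* **e** — residual. RNM1: Var(e) = σ²_e. RNM2:
  Var(e_ij) = exp(d0 + d1 θ̂_i). RNM1 is implemented as RNM2 with d1
  fixed at 0 and σ²_e = exp(d0), so one code path serves both; the MME
  weight each record by 1/Var(e_ij).

Record editing before any modelling: CGs with fewer than 10 records are
removed, then records further than 3.5 SD from the trait mean (mean and
SD computed at that point) are removed.

## Relationship matrices

* **A** by the tabular method; inbreeding F from a memoised coancestry
  recursion (Meuwissen–Luo style); A⁻¹ by Henderson's rules with
  inbreeding-corrected Mendelian-sampling variances.
* **G** by VanRaden method 1, `Z Zᵀ / (2 Σ p(1−p))`, with observed
  allele frequencies by default (a supplied-frequency option exists).
  Before inversion G is blended as (1−w)G + w·A22 with w = 0.05 by
  default — the construction method and blending are not published for
  this analysis; these are the standard defaults and are configurable.
* **H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]** exactly; no τ/ω scaling of the
  correction block.
* **X chromosome**: X SNPs enter G like autosomal SNPs under the male
  {0, 2} hemizygote coding; an `include_x=False` switch removes them.
  Sex-specific X relationship matrices are out of scope and documented
  as such — the field itself treats the right construction as open.
* Genotype QC: keep a SNP when call rate > 0.90, MAF > 0.01 and the
  difference between observed and expected (2p(1−p)) heterozygote
  frequencies < 0.15; animals need call rate ≥ 0.90. For X SNPs the
  heterozygosity check uses females only, since hemizygous males are
  never heterozygous under the {0, 2} coding and would otherwise
  inflate the difference mechanically.

Matrices are dense; the implementation targets populations up to a few
thousand animals, which all shipped analyses and tests stay inside.

## AI-REML

The restricted log-likelihood is computed from the mixed-model
equations as −½(log|R| + log|G| + log|C| + y′Py) — with the additive
constant omitted, matching the dense form
−½(log|V| + log|X′V⁻¹X| + y′Py); the two are verified against each
other to 10⁻⁶ in the tests. AIC = −2 logL + 2k with k the number of
estimated (co)variance parameters only (3 per block, plus d0, plus d1
under RNM2) — the REML likelihood already profiles out the fixed
effects, so they are not counted; ties go to the homogeneous model.

Optimization runs on an unconstrained scale: log variances, Fisher-z
transformed block correlations (clipped at |r| = 0.9999, the value
reported when an estimate sits on the boundary), raw d0 and d1. Scores
and average-information entries are assembled from the full inverse of
the coefficient matrix (LAPACK `potrf`/`potri` once per iteration) and
from working vectors solved against the same factorization; the exact
analytic gradient was verified against finite differences.

Step control is Levenberg-style: the AI step is damped by an adaptive
ridge that grows until the restricted likelihood improves, components
pushing against an active bound are projected out, and per-parameter
moves are capped at 3 on the log scale. If no damped AI step improves,
an EM update of the covariance blocks is tried. Convergence is declared
when the largest relative parameter change drops below 1e-8, the logL
change drops below 1e-9, or the projected gradient's infinity norm
drops below 0.01. The third criterion exists because boundary optima
(slope variance near zero with |r| pinned) otherwise crawl: each EM
micro-step still improves logL by ~1e-7 and the first two criteria
never fire. At 0.01 the remaining parameter motion is orders of
magnitude below one standard error. Accepted iterations never decrease
logL.

Starting values: half the phenotypic variance on the additive
intercept, 10 % on every other component, zero covariances, d1 = 0,
and the residual takes the remainder (at least 20 %).

Standard errors of the variance parameters come from the inverse AI
matrix at the optimum, on the original (variance/covariance and d)
scale; solution standard errors are square roots of the corresponding
diagonal of C⁻¹, as the accuracy formula requires.

## Downstream quantities

* Additive variance σ̂²_u(θ) = [1, θ] B_a [1, θ]′; heritability divides
  by the same quadratic form summed over all fitted blocks plus the
  residual variance at θ. Curves are evaluated on 101 equally spaced
  points across the retained gradient range by default.
* Genetic correlation between environments uses the bilinear form of
  B_a; the reported "extreme-environment" value is r(θ_min, θ_max) over
  retained CGs, and the "average" is the mean over distinct grid pairs
  — labelled a convention, since published averaging sets for such
  summaries vary.
* Accuracy: Acc_j = √(1 − SE²_j/((1+F_j) σ̂²)) with pedigree-based F_j
  and the *population* variance of the respective coefficient (σ̂²_a0
  or σ̂²_a1); the per-animal subscript in the published formula is read
  as "coefficient of animal j", not an animal-specific variance. The
  radicand is clamped to [0, 1].
* Weighted GEBV correlation: the published weight expression
  (Acc²_x Acc²_y)/√(Acc²_x Acc²_y) simplifies algebraically to
  Acc_x·Acc_y, which is what is computed; animals must exceed accuracy
  0.35 on both traits, and SE(r̂) = √((1−r̂²)/(n−2)).
* Re-ranking: Spearman correlations (average-rank ties) of GEBV(θ) at
  the 15/50/85 % gradient quantiles among animals with more than 10
  offspring and accuracies above 0.30; sire trajectories take the 20
  highest- and lowest-slope sires with strictly more than 30 offspring.
* ssGWAS: û = Z′(ZZ′)⁻¹â per coefficient with identity SNP weighting
  (pseudo-inverse when ZZ′ is singular — which happens whenever
  genotyped animals outnumber SNPs). Window score: the variance across
  genotyped animals of the 5-SNP windowed genomic value, as a percent
  of that coefficient's additive variance (intercept windows against
  σ̂²_a0, slope windows against σ̂²_a1). The alternative
  sum-of-squared-effects convention is *not* used; the variance-of-
  window-value convention is the one implemented by the standard
  post-analysis tools. "Adjacent" means map-order adjacency after QC;
  windows never span chromosomes; windows ≥ 0.5 % are relevant and
  overlapping relevant windows merge into regions (1-based inclusive
  bp).

## Synthetic data

The generator produces the study's assumed data-generating process,
not a particular real population:

* discrete generations, random mating of sampled sires to sampled dams,
  Poisson litter sizes, full-sib litters sharing a birth-litter (ce)
  code; founder count, generations, matings per generation and litter
  size are configurable because real mating designs of nucleus herds
  are not public;
* gene dropping from founder allele frequencies drawn uniformly on a
  configurable MAF range; autosomes segregate Mendelian, X-linked loci
  follow sex-specific transmission with male dosages on {0, 2}; a
  genotyped subset is drawn with weights increasing quadratically with
  generation, mimicking recent-generation genotyping and exercising the
  H⁻¹ correction non-trivially;
* additive (intercept, slope) pairs propagate through the pedigree by
  the gene-flow recursion a_j = ½(a_s + a_d) + m_j with
  Var(m_j) = (0.5 − 0.25(F_s + F_d))·B_a, giving Cov = A ⊗ B_a exactly;
  pe pairs are i.i.d. per animal, ce pairs i.i.d. per litter; the true
  gradient is drawn standard normal per CG and standardized, and CG
  membership per record is drawn with heterogeneous weights from a
  configurable size range;
* residuals are homogeneous or exp(d0 + d1 θ); every true effect and
  parameter is returned in a truth object.

Not emulated: linkage disequilibrium and marker linkage (loci segregate
independently), mutation, selection, genotyping error, missing
genotypes needing imputation. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions — they do not certify behaviour under LD structure or
selection, which real data have.

A small helper (`inject_qtl`) adds a single-SNP effect on the intercept
and/or slope to an existing simulated dataset, which is how the
association scan's localization behaviour is exercised.

## Test problem sizes and tolerances

Worked examples and matrix oracles run at desk scale (≤ 30 records,
≤ 25 animals, tolerances 1e-12 … 1e-6 as the quantity warrants).
Parameter recovery uses ten replicates of a 1500-animal pedigree, 30
CGs and three records per non-founder with the litter-size additive
block as truth and residual exp(d0) = 2 (intercept h² ≈ 0.33, three
times the raw-trait heritability of litter size): the residual scale
was chosen so the Fisher information at 1500 animals actually
identifies the slope parameters — at a litter-size-realistic residual
the likelihood is flat enough that boundary estimates, not truth
recovery, are the correct REML answer, and a recovery test would be
meaningless. Model-selection, QTL-localization and pipeline checks use
300–900-animal populations sized to finish the whole suite in a few
minutes on one CPU.

## Known limitations

* Dense linear algebra throughout: pedigrees beyond ~5000 animals or
  panels beyond ~10⁴ SNPs need the sparse/iterative machinery of the
  dedicated breeding-software ecosystems.
* The null-data behaviour of cross-environment correlations is
  intrinsically boundary-driven: with a truly zero slope variance, the
  fitted block either collapses to the PSD-cone boundary (correlations
  ≈ 1) or retains a small interior slope variance that pulls extreme-
  pair correlations visibly below 1. Declaring "no G×E" from a single
  fit should always consult the slope-variance significance test, not
  the correlation alone.
* Single-trait only; no multi-trait reaction norms, no Bayesian
  (Gibbs) estimation, no higher-order polynomial norms, no iterated
  SNP-variance weighting in the association scan.
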