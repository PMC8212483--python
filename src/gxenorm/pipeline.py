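"""End-to-end driver: filters → QC → gradient → REML → parameters → GWAS.

``run_pipeline`` chains every stage of the reaction-norm analysis on a
configured dataset and emits the result tables plus a machine-readable
summary; ``run_analysis`` is the in-memory core, usable directly from
Python with already-loaded objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import envgrad, gebv, genpar, io, relmat, rnm, ssgwas
from .config import RunConfig

__all__ = ["load_dataset", "run_analysis", "run_pipeline", "PipelineResult"]


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def load_dataset(config: RunConfig):
    """Read and cross-validate pedigree, genotypes and phenotypes."""
    ped = io.read_pedigree(config.pedigree_file)
    pheno = io.read_phenotypes(
        config.phenotype_file,
        factors=config.factors,
        covariates=list(config.covariates),
    )
    geno = None
    if config.dosage_file:
        geno = io.read_genotypes(config.dosage_file, config.snp_map_file)
        known = set(ped.animals.tolist())
        orphans = [a for a in geno.ids.tolist() if a not in known]
        if orphans:
            raise ValueError(
                f"genotyped animals absent from the pedigree: {orphans[:10]}"
            )
    known = set(ped.animals.tolist())
    orphans = sorted(set(pheno.df["animal"]) - known)
    if orphans:
        raise ValueError(
            f"phenotyped animals absent from the pedigree: {orphans[:10]}"
        )
    return ped, geno, pheno


@dataclass
class PipelineResult:
    summary: dict
    gradient: envgrad.EnvGradient
    varcomp: rnm.VarCompSet
    fit: rnm.RNMFit
    fits: dict  # model name -> (VarCompSet, RNMFit)
    curve: genpar.ParameterCurve
    gebv_table: gebv.GEBVTable
    windows: pd.DataFrame | None
    regions: dict | None  # coefficient -> DataFrame
    qc_report: relmat.QCReport | None
    filter_log: dict


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def run_analysis(
    ped: relmat.Pedigree,
    geno: relmat.GenotypeMatrix | None,
    pheno: envgrad.PhenotypeTable,
    config: RunConfig,
    reml_kwargs: dict | None = None,
) -> PipelineResult:
    reml_kwargs = dict(reml_kwargs or {})

    # 1. record filters -------------------------------------------------
    try:
        pheno_f, filter_log = envgrad.apply_record_filters(
            pheno, min_cg=config.min_cg, sd_cut=config.sd_cut
        )
    except Exception as e:
        raise PipelineError("record_filters", e) from e

    # 2. genotype QC ----------------------------------------------------
    qc_report = None
    if geno is not None:
        try:
            if not config.include_x:
                geno = geno.exclude_x()
            geno, qc_report = relmat.qc_genotypes(
                geno,
                call_rate_min=config.call_rate_min,
                maf_min=config.maf_min,
                het_diff_max=config.het_diff_max,
            )
        except Exception as e:
            raise PipelineError("genotype_qc", e) from e

    # 3. model terms ----------------------------------------------------
    spec = envgrad.ModelSpec(
        factors=list(config.factors),
        covariates=dict(config.covariates),
        random_effects=tuple(config.random_effects),
    )
    if config.select_fixed:
        try:
            spec = envgrad.select_fixed_effects(pheno_f, spec)
        except Exception as e:
            raise PipelineError("fixed_effect_selection", e) from e

    # 4. environmental gradient -----------------------------------------
    try:
        gradient = envgrad.build_gradient(pheno_f, spec, sd_cut=config.sd_cut)
        retained = set(gradient.theta.index)
        keep = pheno_f.df["cg"].astype(str).isin(retained)
        if not keep.all():
            filter_log["dropped_gradient_cg"] = int((~keep).sum())
            from dataclasses import replace

            pheno_f = replace(pheno_f, df=pheno_f.df[keep].reset_index(drop=True))
    except Exception as e:
        raise PipelineError("environmental_gradient", e) from e

    # 5. relationship matrices ------------------------------------------
    try:
        ainv = relmat.build_A_inverse(ped)
        if geno is not None and geno.n_animals >= 2:
            A, _ = relmat.build_A(ped)
            a22 = A.subset(geno.ids)
            a22.kind = "A22"
            G = relmat.build_G(
                geno, blend_a22=a22, blend_weight=config.blend_weight
            )
            hinv = relmat.build_Hinv(
                ainv,
                relmat.invert_relationship(a22, "A22inv"),
                relmat.invert_relationship(G, "Ginv"),
                geno.ids,
            )
        else:
            hinv = relmat.RelationshipMatrix(ainv.ids, ainv.to_dense(), "Hinv")
    except Exception as e:
        raise PipelineError("relationship_matrices", e) from e

    # 6. REML fits and model choice -------------------------------------
    fits = {}
    try:
        models = ("RNM1", "RNM2") if config.model == "auto" else (config.model,)
        for m in models:
            fits[m] = rnm.reml_fit(
                pheno_f, gradient, spec, hinv, model=m,
                cg_as_class=config.cg_as_class, **reml_kwargs,
            )
        if len(fits) == 2:
            chosen = rnm.choose_model(fits["RNM1"][1], fits["RNM2"][1])
        else:
            chosen = models[0]
        varcomp, fit = fits[chosen]
    except Exception as e:
        raise PipelineError("reml", e) from e

    # 7. genetic parameters ---------------------------------------------
    try:
        lo, hi = gradient.range
        curve = genpar.parameter_curve(varcomp, lo, hi)
        B = varcomp.block("a")
        grid = np.linspace(lo, hi, 21)
        cmat = genpar.env_correlation_matrix(B, grid).to_numpy()
        min_corr = float(cmat.min())
        extreme_corr = genpar.env_genetic_correlation(B, lo, hi)
        is_corr = genpar.intercept_slope_correlation(B)
    except Exception as e:
        raise PipelineError("genetic_parameters", e) from e

    # 8. GEBV diagnostics -----------------------------------------------
    try:
        gtab = gebv.gebv_table_from_fit(fit, varcomp, ped)
        try:
            spearman = gebv.rank_stability(
                gtab, gradient,
                min_offspring=config.min_offspring_ranking,
                min_acc=config.acc_min_ranking,
            )
        except ValueError:
            spearman = None
    except Exception as e:
        raise PipelineError("gebv", e) from e

    # 9. ssGWAS ----------------------------------------------------------
    windows = None
    regions = None
    if geno is not None and geno.n_snps >= config.window_size:
        try:
            Z = geno.centered()
            sols = gtab.table.set_index("animal")
            a0 = sols["a0"].reindex(geno.ids).to_numpy()
            a1 = sols["a1"].reindex(geno.ids).to_numpy()
            u0 = ssgwas.backsolve_snp_effects(Z, a0)
            u1 = ssgwas.backsolve_snp_effects(Z, a1)
            eff = ssgwas.snp_effect_table(geno, u0, u1)
            windows = ssgwas.window_variance_proportions(
                eff, Z, B[0, 0], B[1, 1], window=config.window_size
            )
            regions = {
                c: ssgwas.find_relevant_regions(
                    windows, config.relevance_percent, c
                )
                for c in ("intercept", "slope")
            }
        except Exception as e:
            raise PipelineError("ssgwas", e) from e

    slope_var = float(B[1, 1])
    slope_se = varcomp.se.get("a_var1", float("nan"))
    summary = {
        "chosen_model": chosen,
        "aic": {m: fits[m][1].aic for m in fits},
        "loglik": {m: fits[m][1].loglik for m in fits},
        "n_records": fit.n_records,
        "n_cg_retained": int(gradient.table["kept"].sum()),
        "gradient_range": [lo, hi],
        "blocks": {e: varcomp.block(e).tolist() for e in varcomp.blocks},
        "residual": {
            "kind": varcomp.residual_kind,
            "d0": varcomp.d0,
            "d1": varcomp.d1,
        },
        "parameter_se": dict(varcomp.se),
        "slope_variance": slope_var,
        "slope_variance_se": slope_se,
        "slope_significant": bool(
            np.isfinite(slope_se) and slope_se > 0 and slope_var / slope_se > 1.645
        ),
        "intercept_slope_correlation": is_corr,
        "extreme_env_correlation": extreme_corr,
        "min_env_correlation": min_corr,
        "h2_range": [float(curve.table["h2"].min()),
                     float(curve.table["h2"].max())],
        "spearman": None if spearman is None else spearman.to_dict(),
        "n_relevant_regions": None if regions is None else {
            c: int(len(r)) for c, r in regions.items()
        },
        "filter_log": {k: v for k, v in filter_log.items() if k != "small_cgs"},
    }
    return PipelineResult(
        summary=summary,
        gradient=gradient,
        varcomp=varcomp,
        fit=fit,
        fits=fits,
        curve=curve,
        gebv_table=gtab,
        windows=windows,
        regions=regions,
        qc_report=qc_report,
        filter_log=filter_log,
    )


def run_pipeline(config: RunConfig, reml_kwargs: dict | None = None) -> PipelineResult:
    """Load the configured dataset, run the analysis, write all outputs."""
    try:
        ped, geno, pheno = load_dataset(config)
    except Exception as e:
        raise PipelineError("load_dataset", e) from e
    result = run_analysis(ped, geno, pheno, config, reml_kwargs=reml_kwargs)
    if config.output_dir:
        write_outputs(Path(config.output_dir), result)
    return result


def write_outputs(outdir: Path, result: PipelineResult) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(
        outdir / "gradient.tsv",
        result.gradient.table,
        ["environmental gradient: standardized CG effects (mean 0, SD 1), "
         "unitless"],
    )
    vc = result.varcomp
    rows = [
        (eff, nm, float(v), vc.se.get(f"{eff}_{nm}", float("nan")))
        for eff in vc.blocks
        for nm, v in (
            ("var0", vc.block(eff)[0, 0]),
            ("cov01", vc.block(eff)[0, 1]),
            ("var1", vc.block(eff)[1, 1]),
        )
    ]
    rows.append(("residual", "d0", vc.d0, vc.se.get("d0", float("nan"))))
    if vc.residual_kind == "heteroscedastic":
        rows.append(("residual", "d1", vc.d1, vc.se.get("d1", float("nan"))))
    io.write_table(
        outdir / "varcomp.tsv",
        pd.DataFrame(rows, columns=["effect", "param", "estimate", "se"]),
        ["variance components on the trait-units² scale; residual is "
         "exp(d0 + d1*theta)"],
    )
    sols = result.fit.solutions_for("a")
    io.write_table(
        outdir / "solutions_a.tsv", sols,
        ["additive intercept/slope solutions with SE from the inverse "
         "left-hand side"],
    )
    io.write_table(
        outdir / "curve.tsv", result.curve.table,
        ["genetic parameters along the gradient; theta unitless "
         "(standardized CG effect)"],
    )
    io.write_table(
        outdir / "gebv.tsv", result.gebv_table.table,
        ["per-animal GEBV: GEBV(theta) = a0 + a1*theta; accuracies from "
         "Acc = sqrt(1 - SE^2/((1+F)*var))"],
    )
    if result.windows is not None:
        io.write_table(
            outdir / "windows.tsv", result.windows,
            ["5-SNP sliding windows; positions 1-based inclusive bp; "
             "pct columns are % of the coefficient's additive variance"],
        )
        for coef, reg in result.regions.items():
            io.write_table(
                outdir / f"regions_{coef}.tsv", reg,
                ["candidate regions from merged overlapping relevant "
                 "windows; 1-based inclusive bp"],
            )
    if result.qc_report is not None:
        io.write_table(
            outdir / "qc_snps.tsv", result.qc_report.snp_metrics,
            ["per-SNP QC metrics; kept=False rows give the removal reason"],
        )
    io.write_summary(outdir / "summary.json", result.summary)
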