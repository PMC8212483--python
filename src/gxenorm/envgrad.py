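"""Record filters, model-term selection and the environmental gradient.

The environmental descriptor is the standardized contemporary-group
(CG) effect: CG effects are estimated by BLUE from a fixed-effects-only
linear model containing all retained systematic effects, then z-scored
(mean 0, SD 1); CGs further than 3.5 SD from the mean are dropped and
the remainder re-standardized.  The resulting θ̂ per CG is the
covariate on which each animal's genetic merit is regressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeTable",
    "ModelSpec",
    "EnvGradient",
    "apply_record_filters",
    "select_fixed_effects",
    "select_random_effects",
    "estimate_cg_effects",
    "standardize_gradient",
    "build_gradient",
]


@dataclass
class PhenotypeTable:
    """Phenotype records with declared column roles.

    ``df`` must contain ``animal``, ``y`` and ``cg`` columns; ``litter``
    is needed only when a litter (ce) effect is fitted.  ``factors`` and
    ``covariates`` name the candidate systematic-effect columns.
    """

    df: pd.DataFrame
    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    trait: str = "trait"

    def __post_init__(self) -> None:
        for c in ("animal", "y", "cg"):
            if c not in self.df.columns:
                raise ValueError(f"phenotype table missing column {c!r}")
        if len(self.df) == 0:
            raise ValueError("phenotype table is empty")
        if not np.isfinite(self.df["y"]).all():
            raise ValueError("non-finite trait values present")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ModelSpec:
    """Retained model terms.

    ``covariates`` maps a column name to its highest retained power
    (1 = linear, 2 = linear + quadratic).  The additive genetic effect
    is always part of ``random_effects``.
    """

    factors: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)
    random_effects: tuple = ("a",)

    def __post_init__(self) -> None:
        if "a" not in self.random_effects:
            raise ValueError("the additive effect 'a' must always be fitted")
        bad = set(self.random_effects) - {"a", "pe", "ce"}
        if bad:
            raise ValueError(f"unknown random effects: {sorted(bad)}")

    def covariate_terms(self):
        """[(column, power), ...] in a stable order."""
        out = []
        for name, pmax in self.covariates.items():
            for p in range(1, int(pmax) + 1):
                out.append((name, p))
        return out


@dataclass
class EnvGradient:
    """Standardized CG effects: the environmental gradient θ̂."""

    table: pd.DataFrame  # cg, raw, theta, n, kept

    def __post_init__(self) -> None:
        kept = self.table.loc[self.table["kept"], "theta"]
        if len(kept) >= 2:
            if abs(kept.mean()) > 1e-8 or abs(kept.std(ddof=1) - 1.0) > 1e-8:
                raise ValueError("retained θ̂ must have mean 0 and SD 1")

    @property
    def theta(self) -> pd.Series:
        t = self.table.loc[self.table["kept"]]
        return pd.Series(t["theta"].to_numpy(), index=t["cg"].to_numpy())

    def theta_for(self, cgs) -> np.ndarray:
        mapping = self.theta
        vals = mapping.reindex(np.asarray(cgs))
        if vals.isna().any():
            missing = sorted(set(np.asarray(cgs)) - set(mapping.index))
            raise KeyError(f"no retained gradient value for CGs: {missing[:10]}")
        return vals.to_numpy()

    @property
    def range(self) -> tuple[float, float]:
        t = self.theta.to_numpy()
        return float(t.min()), float(t.max())


# ---------------------------------------------------------------------------
# record filters


def apply_record_filters(
    pheno: PhenotypeTable, min_cg: int = 10, sd_cut: float = 3.5
) -> tuple[PhenotypeTable, dict]:
    """Drop small CGs, then trait outliers beyond ``sd_cut`` SD of the mean.

    The outlier mean/SD are computed on the table as it stands before
    outlier removal.  Returns the filtered table and a log of counts.
    """
    df = pheno.df
    n_in = len(df)
    sizes = df.groupby("cg")["y"].size()
    small = set(sizes.index[sizes < min_cg])
    df1 = df[~df["cg"].isin(small)]
    n_small = n_in - len(df1)
    if len(df1) == 0:
        raise ValueError("record filters removed every record (CG size rule)")
    mu, sd = df1["y"].mean(), df1["y"].std(ddof=1)
    if sd > 0:
        keep = (df1["y"] - mu).abs() <= sd_cut * sd
    else:
        keep = np.ones(len(df1), dtype=bool)
    df2 = df1[keep]
    log = {
        "records_in": n_in,
        "dropped_small_cg": n_small,
        "small_cgs": sorted(small),
        "dropped_outliers": int(len(df1) - len(df2)),
        "records_out": len(df2),
    }
    if len(df2) == 0:
        raise ValueError("record filters removed every record (outlier rule)")
    return replace(pheno, df=df2.reset_index(drop=True)), log


# ---------------------------------------------------------------------------
# fixed-effect design helpers


def _design_columns(df, spec: ModelSpec, cg: bool, cg_sum_to_zero: bool):
    """Fixed-effects design matrix (full rank) and column names."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in spec.factors:
        levels = sorted(df[f].astype(str).unique())
        for lev in levels[1:]:  # treatment coding, first level as reference
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    for name, p in spec.covariate_terms():
        v = df[name].to_numpy(float)
        cols.append(v**p)
        names.append(name if p == 1 else f"{name}^{p}")
    if cg:
        levels = sorted(df["cg"].astype(str).unique())
        if cg_sum_to_zero:
            # deviation coding: K−1 columns, last level coded −1 everywhere
            last = df["cg"].astype(str) == levels[-1]
            for lev in levels[:-1]:
                col = (df["cg"].astype(str) == lev).to_numpy(float)
                col[last.to_numpy()] = -1.0
                cols.append(col)
                names.append(f"cg[{lev}]")
        else:
            for lev in levels[1:]:
                cols.append((df["cg"].astype(str) == lev).to_numpy(float))
                names.append(f"cg[{lev}]")
    return np.column_stack(cols), names


def _term_column_map(names):
    """Group design columns by model term (factor or covariate power)."""
    groups: dict[str, list[int]] = {}
    for j, nm in enumerate(names):
        if nm == "intercept":
            continue
        term = nm.split("[")[0] if "[" in nm else nm
        groups.setdefault(term, []).append(j)
    return groups


def select_fixed_effects(
    pheno: PhenotypeTable, candidates: ModelSpec, alpha: float = 0.05
) -> ModelSpec:
    """Backward elimination of fixed effects by partial F-tests.

    Repeatedly drops the least significant non-CG term with P ≥ alpha
    until every remaining term is significant.  The CG effect is always
    retained, and a linear covariate is only droppable once its
    quadratic term is gone.
    """
    spec = replace(
        candidates,
        factors=list(candidates.factors),
        covariates=dict(candidates.covariates),
    )
    df = pheno.df
    y = df["y"].to_numpy(float)
    while True:
        X, names = _design_columns(df, spec, cg=True, cg_sum_to_zero=True)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                "rank-deficient fixed-effect design; confounded terms among: "
                f"{[n for n in names if n != 'intercept']}"
            )
        beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss_full = float(resid @ resid)
        df_resid = len(y) - X.shape[1]
        groups = _term_column_map(names)
        droppable = []
        for term, idx in groups.items():
            if term.startswith("cg"):
                continue
            if term in spec.covariates and spec.covariates[term] > 1:
                continue  # hierarchy: test the quadratic first
            droppable.append((term, idx))
        for name, pmax in spec.covariates.items():
            if pmax > 1:
                droppable.append((f"{name}^{int(pmax)}", groups[f"{name}^{int(pmax)}"]))
        if not droppable:
            return spec
        worst, worst_p = None, -1.0
        for term, idx in droppable:
            keep = [j for j in range(X.shape[1]) if j not in idx]
            Xr = X[:, keep]
            br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
            rr = y - Xr @ br
            rss_red = float(rr @ rr)
            fstat = ((rss_red - rss_full) / len(idx)) / (rss_full / df_resid)
            p = float(stats.f.sf(max(fstat, 0.0), len(idx), df_resid))
            if p > worst_p:
                worst, worst_p = term, p
        if worst_p < alpha:
            return spec
        if "^" in worst:
            base = worst.split("^")[0]
            spec.covariates[base] = 1
        elif worst in spec.covariates:
            del spec.covariates[worst]
        else:
            spec.factors.remove(worst)


def select_random_effects(
    pheno: PhenotypeTable,
    gradient: "EnvGradient",
    specs,
    hinv,
    model: str = "RNM1",
    **fit_kwargs,
):
    """Fit each candidate random-effect structure; keep the lowest AIC."""
    from . import rnm  # local import to avoid a cycle

    specs = list(specs)
    if not specs:
        raise ValueError("no candidate specifications given")
    if len(specs) == 1:
        return specs[0]
    best, best_aic = None, np.inf
    for spec in specs:
        _, fit = rnm.reml_fit(pheno, gradient, spec, hinv, model=model, **fit_kwargs)
        if fit.aic < best_aic:
            best, best_aic = spec, fit.aic
    return best


# ---------------------------------------------------------------------------
# CG effects and the gradient


def estimate_cg_effects(pheno: PhenotypeTable, spec: ModelSpec) -> pd.Series:
    """BLUE of CG effects from a fixed-effects-only linear model.

    Ordinary least squares on all systematic effects plus CG under a
    sum-to-zero constraint, so the raw estimates are centred and ready
    for standardization.
    """
    df = pheno.df
    y = df["y"].to_numpy(float)
    X, names = _design_columns(df, spec, cg=True, cg_sum_to_zero=True)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # try to name the culprit: drop CG columns and re-check
        Xnc, _ = _design_columns(df, spec, cg=False, cg_sum_to_zero=False)
        if np.linalg.matrix_rank(Xnc) == Xnc.shape[1]:
            raise ValueError(
                "CG effect confounded with another systematic effect"
            )
        raise ValueError("rank-deficient design among systematic effects")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    levels = sorted(df["cg"].astype(str).unique())
    if len(levels) == 1:
        return pd.Series([0.0], index=levels)
    est = {}
    for nm, b in zip(names, beta):
        if nm.startswith("cg["):
            est[nm[3:-1]] = float(b)
    est[levels[-1]] = -sum(est.values())
    return pd.Series([est[l] for l in levels], index=levels)


def standardize_gradient(raw: pd.Series, sd_cut: float = 3.5) -> EnvGradient:
    """z-score CG estimates, drop |z| > sd_cut, re-standardize the rest."""
    raw = pd.Series(raw, dtype=float)
    if len(raw) < 2:
        raise ValueError("need at least two CGs to standardize a gradient")
    if raw.std(ddof=1) == 0:
        raise ValueError("CG estimates have zero variance")
    z = (raw - raw.mean()) / raw.std(ddof=1)
    kept = z.abs() <= sd_cut
    zin = raw[kept]
    if kept.sum() < 2 or zin.std(ddof=1) == 0:
        raise ValueError("fewer than two CGs retained by the 3.5-SD rule")
    theta = (zin - zin.mean()) / zin.std(ddof=1)
    table = pd.DataFrame(
        {
            "cg": raw.index,
            "raw": raw.to_numpy(),
            "theta": theta.reindex(raw.index).to_numpy(),
            "kept": kept.to_numpy(),
        }
    )
    return EnvGradient(table)


def build_gradient(
    pheno: PhenotypeTable, spec: ModelSpec, sd_cut: float = 3.5
) -> EnvGradient:
    """estimate_cg_effects + standardize_gradient, with CG record counts."""
    raw = estimate_cg_effects(pheno, spec)
    grad = standardize_gradient(raw, sd_cut=sd_cut)
    counts = pheno.df.groupby("cg")["y"].size()
    grad.table["n"] = counts.reindex(grad.table["cg"]).fillna(0).to_numpy(int)
    return grad
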