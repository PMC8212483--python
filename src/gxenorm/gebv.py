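"""Breeding-value diagnostics across the environmental gradient.

Each animal carries two genomic breeding values — a reaction-norm
intercept and slope — combined as GEBV(θ) = â0 + â1·θ.  This module
computes prediction accuracies from the solution standard errors,
weighted Pearson correlations of GEBV between traits, Spearman
re-ranking between representative environments, and the reaction-norm
trajectories of extreme-slope sires.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GEBVTable",
    "CorrelationEstimate",
    "gebv_table_from_fit",
    "gebv_at",
    "accuracy",
    "weighted_gebv_correlation",
    "rank_stability",
    "sire_trajectories",
]


@dataclass
class GEBVTable:
    """Per-animal intercept/slope GEBV with standard errors."""

    table: pd.DataFrame  # animal, a0, a1, se0, se1, acc0, acc1, n_offspring

    def __post_init__(self) -> None:
        req = {"animal", "a0", "a1", "se0", "se1"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"GEBV table missing columns: {sorted(missing)}")


def accuracy(se, F, var_coeff):
    """Acc = √(1 − SE² / ((1 + F) σ²)), clamped into [0, 1].

    ``se`` is the prediction standard error of the coefficient (from the
    inverse of the mixed-model left-hand side), ``F`` the animal's
    pedigree inbreeding coefficient and ``var_coeff`` the additive
    variance of that coefficient (σ²_a0 or σ²_a1).
    """
    var_coeff = np.asarray(var_coeff, dtype=float)
    if np.any(var_coeff <= 0):
        raise ValueError("coefficient variance must be positive")
    se = np.asarray(se, dtype=float)
    F = np.asarray(F, dtype=float)
    radicand = np.clip(1.0 - se**2 / ((1.0 + F) * var_coeff), 0.0, 1.0)
    out = np.sqrt(radicand)
    return float(out) if out.ndim == 0 else out


def gebv_table_from_fit(fit, varcomp, pedigree) -> GEBVTable:
    """Assemble the GEBV table from a REML fit, with accuracies.

    Inbreeding coefficients are pedigree-based; the coefficient variance
    in the accuracy formula is the population additive variance of the
    respective reaction-norm coefficient.
    """
    sols = fit.solutions_for("a")
    F = pd.Series(pedigree.inbreeding(), index=pedigree.animals)
    B = varcomp.block("a")
    t = pd.DataFrame(
        {
            "animal": sols["id"],
            "a0": sols["intercept"].to_numpy(),
            "a1": sols["slope"].to_numpy(),
            "se0": sols["se_int"].to_numpy(),
            "se1": sols["se_slo"].to_numpy(),
        }
    )
    Fv = F.reindex(t["animal"]).fillna(0.0).to_numpy()
    t["acc0"] = accuracy(t["se0"].to_numpy(), Fv, B[0, 0])
    t["acc1"] = accuracy(t["se1"].to_numpy(), Fv, B[1, 1])
    t["n_offspring"] = (
        pedigree.offspring_counts().reindex(t["animal"]).fillna(0).to_numpy(int)
    )
    return GEBVTable(t)


def gebv_at(table: GEBVTable, theta: float) -> pd.Series:
    """GEBV(θ) = â0 + â1·θ per animal."""
    t = table.table
    return pd.Series(
        (t["a0"] + t["a1"] * theta).to_numpy(), index=t["animal"].to_numpy()
    )


@dataclass
class CorrelationEstimate:
    r: float
    se: float
    n: int
    min_acc: float


def weighted_gebv_correlation(
    x, y, acc_x, acc_y, min_acc: float = 0.35
) -> CorrelationEstimate:
    """Accuracy-weighted Pearson correlation of GEBV between two traits.

    Animals must exceed ``min_acc`` on both traits; each kept animal is
    weighted by Acc_x·Acc_y (the algebraic value of the published
    weight expression).  The SE is √((1 − r²)/(n − 2)) with n the number
    of selected animals.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    acc_x, acc_y = np.asarray(acc_x, float), np.asarray(acc_y, float)
    sel = (acc_x > min_acc) & (acc_y > min_acc)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(
            f"only {n} animals exceed accuracy {min_acc} on both traits"
        )
    w = acc_x[sel] * acc_y[sel]
    xs, ys = x[sel], y[sel]
    xbar = np.sum(w * xs) / np.sum(w)
    ybar = np.sum(w * ys) / np.sum(w)
    cov = np.sum(w * (xs - xbar) * (ys - ybar)) / np.sum(w)
    vx = np.sum(w * (xs - xbar) ** 2) / np.sum(w)
    vy = np.sum(w * (ys - ybar) ** 2) / np.sum(w)
    r = float(cov / np.sqrt(vx * vy))
    se = float(np.sqrt(max(1.0 - r**2, 0.0) / (n - 2)))
    return CorrelationEstimate(r=r, se=se, n=n, min_acc=min_acc)


def rank_stability(
    table: GEBVTable,
    gradient,
    quantiles=(0.15, 0.50, 0.85),
    min_offspring: int = 10,
    min_acc: float = 0.30,
) -> pd.DataFrame:
    """Spearman rank correlations of GEBV between gradient quantiles.

    GEBV are evaluated at the θ quantiles of the retained contemporary
    groups, restricted to animals with more than ``min_offspring``
    offspring and accuracy above ``min_acc`` for both coefficients.
    """
    thetas = np.quantile(gradient.theta.to_numpy(), quantiles)
    t = table.table
    ok = t["n_offspring"] > min_offspring
    if "acc0" in t.columns:
        ok &= (t["acc0"] > min_acc) & (t["acc1"] > min_acc)
    sub = t[ok]
    if len(sub) < 2:
        raise ValueError("no qualifying animals for rank-stability analysis")
    vals = [sub["a0"] + sub["a1"] * th for th in thetas]
    k = len(thetas)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rho = stats.spearmanr(vals[i], vals[j]).statistic
            out[i, j] = out[j, i] = rho
    labels = [f"q{int(100 * q)}" for q in quantiles]
    return pd.DataFrame(out, index=labels, columns=labels)


def sire_trajectories(
    table: GEBVTable,
    pedigree,
    gradient,
    min_offspring: int = 30,
    top_k: int = 20,
    n_points: int = 101,
) -> pd.DataFrame:
    """Reaction-norm lines of the extreme-slope sires.

    Considers sires with more than ``min_offspring`` offspring, ranks
    them by slope GEBV and returns GEBV over the gradient range for the
    ``top_k`` highest- and lowest-slope sires (long format).
    """
    t = table.table
    sex = pd.Series(
        pedigree.df["sex"].to_numpy(), index=pedigree.df["animal"].to_numpy()
    )
    males = sex.reindex(t["animal"]).to_numpy() == "M"
    ok = males & (t["n_offspring"].to_numpy() > min_offspring)
    sub = t[ok].sort_values("a1", ascending=False)
    if len(sub) < 2 * top_k:
        warnings.warn(
            f"only {len(sub)} qualifying sires for top/bottom {top_k}; "
            "returning all of them"
        )
        chosen = sub
    else:
        chosen = pd.concat([sub.head(top_k), sub.tail(top_k)])
    lo, hi = gradient.range
    grid = np.linspace(lo, hi, n_points)
    rows = []
    for _, s in chosen.iterrows():
        group = "high_slope" if s["a1"] >= chosen["a1"].median() else "low_slope"
        for th in grid:
            rows.append((s["animal"], group, th, s["a0"] + s["a1"] * th))
    return pd.DataFrame(rows, columns=["animal", "group", "theta", "gebv"])
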