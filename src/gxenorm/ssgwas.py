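"""Single-step GWAS: back-solved SNP effects and sliding-window scans.

SNP effects for the reaction-norm intercept and slope are back-solved
from the genotyped animals' GEBV through the centred genotype matrix,

    û = Zᵀ (Z Zᵀ)⁻¹ â ,

with identity SNP-variance weighting (a pseudo-inverse is used when
Z Zᵀ is singular).  Sliding windows of five map-adjacent SNPs are then
scored by the variance, across genotyped animals, of the windowed
genomic value Σ z_jk û_k, expressed as a percentage of the additive
variance of the corresponding coefficient.  Windows at or above 0.5 %
are relevant; overlapping relevant windows merge into candidate
regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "backsolve_snp_effects",
    "snp_effect_table",
    "window_variance_proportions",
    "find_relevant_regions",
]


def backsolve_snp_effects(Z: np.ndarray, gebv: np.ndarray) -> np.ndarray:
    """û = Zᵀ(Z Zᵀ)⁻¹ â for one vector of GEBV.

    ``Z`` is the column-centred dosage matrix of the genotyped animals
    (animals × SNPs) and ``gebv`` their breeding values for one
    reaction-norm coefficient.
    """
    Z = np.asarray(Z, dtype=float)
    a = np.asarray(gebv, dtype=float)
    if Z.shape[0] != a.shape[0]:
        raise ValueError(
            f"Z has {Z.shape[0]} animals but gebv has {a.shape[0]} entries"
        )
    K = Z @ Z.T
    try:
        x = np.linalg.solve(K, a)
        # guard against ill-conditioned solves masquerading as success
        if not np.allclose(K @ x, a, rtol=1e-6, atol=1e-8 * np.abs(a).max()):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        x = np.linalg.pinv(K) @ a
    return Z.T @ x


def snp_effect_table(geno, u0: np.ndarray, u1: np.ndarray) -> pd.DataFrame:
    """Tidy per-SNP effect table aligned with the SNP map."""
    t = geno.snps[["snp", "chrom", "pos"]].copy()
    t["u0"] = np.asarray(u0, dtype=float)
    t["u1"] = np.asarray(u1, dtype=float)
    return t


def window_variance_proportions(
    effects: pd.DataFrame,
    Z: np.ndarray,
    var_a0: float,
    var_a1: float,
    window: int = 5,
) -> pd.DataFrame:
    """Percent additive variance explained by sliding SNP windows.

    For every run of ``window`` map-adjacent SNPs on one chromosome
    (stride 1), the windowed genomic value g_j = Σ_k z_jk û_k is formed
    per genotyped animal and its variance is expressed as a percentage
    of the additive variance of the matching coefficient — intercept
    percentages against σ²_a0, slope percentages against σ²_a1.
    """
    if var_a0 <= 0 or var_a1 <= 0:
        raise ValueError("additive variances must be positive")
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != len(effects):
        raise ValueError("Z column count does not match the effect table")
    rows = []
    for chrom, idx in effects.groupby("chrom", sort=False).indices.items():
        idx = np.sort(np.asarray(idx))
        if len(idx) < window:
            warnings.warn(
                f"chromosome {chrom} has fewer than {window} SNPs; skipped"
            )
            continue
        pos = effects["pos"].to_numpy()[idx]
        for s in range(len(idx) - window + 1):
            sel = idx[s : s + window]
            Zw = Z[:, sel]
            g0 = Zw @ effects["u0"].to_numpy()[sel]
            g1 = Zw @ effects["u1"].to_numpy()[sel]
            rows.append(
                (
                    chrom,
                    int(pos[s]),
                    int(pos[s + window - 1]),
                    ",".join(effects["snp"].to_numpy()[sel]),
                    100.0 * np.var(g0, ddof=1) / var_a0,
                    100.0 * np.var(g1, ddof=1) / var_a1,
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snps", "pct_int", "pct_slo"]
    )


def find_relevant_regions(
    windows: pd.DataFrame,
    threshold_percent: float = 0.5,
    coefficient: str = "slope",
) -> pd.DataFrame:
    """Merge overlapping windows at/above the threshold into regions.

    Windows are relevant when they explain ``threshold_percent`` or
    more of the additive variance for the chosen coefficient; regions
    never span chromosomes and cover min-start to max-end of their
    supporting windows (1-based inclusive coordinates).
    """
    col = {"intercept": "pct_int", "slope": "pct_slo"}[coefficient]
    rel = windows[windows[col] >= threshold_percent].sort_values(
        ["chrom", "start", "end"]
    )
    regions = []
    for chrom, grp in rel.groupby("chrom", sort=False):
        cur = None
        for _, w in grp.iterrows():
            if cur is not None and w["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n_windows"] += 1
                cur["max_percent"] = max(cur["max_percent"], float(w[col]))
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "max_percent": float(w[col]),
                    "coefficient": coefficient,
                }
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_windows", "max_percent", "coefficient"],
    )
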