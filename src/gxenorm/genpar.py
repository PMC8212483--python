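"""Gradient-dependent genetic parameters from fitted variance components.

Along the environmental gradient θ the additive genetic variance of a
linear reaction norm is the quadratic form

    σ²_u(θ) = σ²_a0 + 2 σ_a0a1 θ + σ²_a1 θ² = [1, θ] B_a [1, θ]ᵀ ,

heritability divides it by the sum of the same quadratic form over all
fitted random effects plus the residual variance at θ, and the genetic
correlation between two environments is the analogous covariance over
the geometric mean of the two variances.  Correlations near 1 across
the gradient mean no genotype-by-environment interaction; values below
0.8 are the conventional evidence for one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rnm import VarCompSet, residual_variance_at

__all__ = [
    "ParameterCurve",
    "additive_variance_at",
    "heritability_at",
    "env_genetic_correlation",
    "intercept_slope_correlation",
    "parameter_curve",
    "env_correlation_matrix",
    "average_env_correlation",
]


def _quad(block: np.ndarray, theta: np.ndarray) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return block[0, 0] + 2.0 * block[0, 1] * theta + block[1, 1] * theta**2


def additive_variance_at(block_a, theta):
    """σ²_u(θ) = [1, θ] B_a [1, θ]ᵀ (vectorized over θ)."""
    out = _quad(block_a, theta)
    return float(out) if np.ndim(theta) == 0 else out


def heritability_at(varcomp: VarCompSet, theta):
    """h²(θ) = additive variance over total (all blocks + residual)."""
    theta = np.asarray(theta, dtype=float)
    num = _quad(varcomp.block("a"), theta)
    denom = sum(_quad(B, theta) for B in varcomp.blocks.values())
    denom = denom + residual_variance_at(varcomp, theta)
    denom = np.asarray(denom, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("total variance is zero at some θ")
    out = num / denom
    return float(out) if theta.ndim == 0 else out


def env_genetic_correlation(block_a, theta_i, theta_j) -> float:
    """Genetic correlation of the trait between environments θ_i and θ_j."""
    B = np.asarray(block_a, dtype=float)
    vi = additive_variance_at(B, theta_i)
    vj = additive_variance_at(B, theta_j)
    if vi <= 0 or vj <= 0:
        raise ValueError("additive variance is zero at one of the environments")
    cov = (
        B[0, 0]
        + B[0, 1] * theta_i
        + B[0, 1] * theta_j
        + B[1, 1] * theta_i * theta_j
    )
    return float(cov / np.sqrt(vi * vj))


def intercept_slope_correlation(block) -> float:
    """σ_a0a1 / √(σ²_a0 σ²_a1): the intrinsic intercept–slope correlation."""
    B = np.asarray(block, dtype=float)
    if B.shape == (3,):  # (var0, cov, var1) triple convenience
        B = np.array([[B[0], B[1]], [B[1], B[2]]])
    if B[0, 0] <= 0 or B[1, 1] <= 0:
        raise ValueError("both intercept and slope variances must be positive")
    return float(B[0, 1] / np.sqrt(B[0, 0] * B[1, 1]))


@dataclass
class ParameterCurve:
    """Per-θ additive, total and residual variances and heritability."""

    table: pd.DataFrame  # theta, var_a, var_total, var_e, h2


def parameter_curve(
    varcomp: VarCompSet,
    theta_min: float,
    theta_max: float,
    n_points: int = 101,
) -> ParameterCurve:
    thetas = np.linspace(theta_min, theta_max, n_points)
    var_a = additive_variance_at(varcomp.block("a"), thetas)
    var_e = np.asarray(residual_variance_at(varcomp, thetas), dtype=float)
    var_total = (
        sum(_quad(B, thetas) for B in varcomp.blocks.values()) + var_e
    )
    return ParameterCurve(
        pd.DataFrame(
            {
                "theta": thetas,
                "var_a": var_a,
                "var_total": var_total,
                "var_e": var_e,
                "h2": var_a / var_total,
            }
        )
    )


def env_correlation_matrix(block_a, thetas) -> pd.DataFrame:
    thetas = np.asarray(thetas, dtype=float)
    n = len(thetas)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = env_genetic_correlation(
                block_a, thetas[i], thetas[j]
            )
    return pd.DataFrame(out, index=thetas, columns=thetas)


def average_env_correlation(block_a, thetas) -> float:
    """Mean genetic correlation over all distinct environment pairs."""
    M = env_correlation_matrix(block_a, thetas).to_numpy()
    iu = np.triu_indices_from(M, k=1)
    return float(M[iu].mean())


def plot_curve(curve: ParameterCurve, ax=None):
    """Plain heritability-vs-gradient plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.table["theta"], curve.table["h2"])
    ax.set_xlabel("environmental gradient θ")
    ax.set_ylabel("heritability h²")
    return ax
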