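"""Shared fixtures: small simulated datasets and a dense-REML oracle.

The dense oracle evaluates the restricted log-likelihood and GLS
solutions directly from the record-level covariance matrix
V = Σ W (B ⊗ K) Wᵀ + R — an independent route against which the
mixed-model-equations implementation is checked.
"""

import numpy as np
import pandas as pd
import pytest

import gxenorm as gx


def hinv_from_ainv(ainv):
    return gx.RelationshipMatrix(ainv.ids, ainv.to_dense(), "Hinv")


def pedigree_only_hinv(ped):
    return hinv_from_ainv(gx.build_A_inverse(ped))


def drop_unretained(pheno, gradient):
    keep = pheno.df["cg"].astype(str).isin(set(gradient.theta.index))
    return gx.PhenotypeTable(
        pheno.df[keep].reset_index(drop=True),
        factors=pheno.factors,
        covariates=pheno.covariates,
    )


def dense_restricted_loglik(sys_, vc, A_dense=None):
    """−½(log|V| + log|XᵀV⁻¹X| + yᵀPy) from the record-level V."""
    n = sys_.n
    theta = sys_.theta
    r = np.exp(vc.d0 + vc.d1 * theta)
    V = np.diag(r)
    if A_dense is None and "a" in sys_.effects:
        A_dense = np.linalg.inv(sys_.hinv)
    for eff in sys_.effects:
        ids = sys_.levels[eff]
        pos = {v: i for i, v in enumerate(ids)}
        key = "litter" if eff == "ce" else "animal"
        col = np.array([pos[v] for v in sys_.records[key]])
        q = len(ids)
        W = np.zeros((n, 2 * q))
        W[np.arange(n), col] = 1.0
        W[np.arange(n), q + col] = theta
        K = np.eye(q) if eff != "a" else A_dense
        V += W @ np.kron(vc.block(eff), K) @ W.T
    Vi = np.linalg.inv(V)
    X, y = sys_.X, sys_.y
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XVX, X.T @ Vi)
    ll = -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + float(y @ P @ y)
    )
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    return ll, beta


@pytest.fixture(scope="session")
def tiny_dataset():
    """~160 animals, all genotyped, a-only truth; fast for unit tests."""
    cfg = gx.SimConfig(
        n_founders=30, n_generations=3, litter_size_mean=5,
        n_matings_per_gen=10, n_cg=12, n_parities=2, seed=42,
        n_auto_snps=90, n_x_snps=6, genotyping_fraction=1.0,
        cg_size_range=(5, 30),
    )
    pars = gx.TrueParameters(
        blocks={"a": np.array([[1.0, 0.2], [0.2, 0.3]])},
        sigma2_e=1.5, b=0.5, mean=10.0, sex_effect=0.4,
    )
    ped, geno, pheno, truth = gx.simulate_dataset(cfg, pars)
    return cfg, pars, ped, geno, pheno, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset):
    """Pedigree-only RNM1 fit of the tiny dataset, shared across tests."""
    _, _, ped, _, pheno, _ = tiny_dataset
    spec = gx.ModelSpec(factors=["sex"], random_effects=("a",))
    grad = gx.build_gradient(pheno, spec)
    pheno_f = drop_unretained(pheno, grad)
    hinv = pedigree_only_hinv(ped)
    vc, fit = gx.reml_fit(pheno_f, grad, spec, hinv, model="RNM1")
    return ped, pheno_f, spec, grad, hinv, vc, fit
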