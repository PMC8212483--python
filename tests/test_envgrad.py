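"""Record filters, CG BLUE estimation and gradient standardization."""

import numpy as np
import pandas as pd
import pytest

import gxenorm as gx
from conftest import drop_unretained, pedigree_only_hinv


def table(df, **kw):
    return gx.PhenotypeTable(pd.DataFrame(df), **kw)


def base_records(n_per_cg, cgs, rng=None, mu=10.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    a = 1
    for cg in cgs:
        for _ in range(n_per_cg[cg]):
            rows.append((a, mu + rng.standard_normal(), cg))
            a += 1
    return pd.DataFrame(rows, columns=["animal", "y", "cg"])


def test_small_cg_removed_entirely():
    df = base_records({"a": 12, "b": 9}, ["a", "b"])
    pheno, log = gx.apply_record_filters(table(df), min_cg=10)
    assert set(pheno.df["cg"]) == {"a"}
    assert log["dropped_small_cg"] == 9
    assert log["records_in"] == log["records_out"] + 9 + log["dropped_outliers"]


def test_outlier_rule_is_3p5_sd():
    rng = np.random.default_rng(1)
    df = base_records({"a": 2000, "b": 2000}, ["a", "b"], rng)
    # standardize the base so the two added records sit at known z-scores
    df["y"] = (df["y"] - df["y"].mean()) / df["y"].std(ddof=1)
    extra = pd.DataFrame(
        {"animal": [9001, 9002], "y": [3.6, 3.4], "cg": ["a", "b"]}
    )
    allrec = pd.concat([df, extra], ignore_index=True)
    pheno, log = gx.apply_record_filters(table(allrec))
    assert 9001 not in set(pheno.df["animal"])
    assert 9002 in set(pheno.df["animal"])


def test_clean_table_unchanged():
    df = base_records({"a": 15, "b": 15}, ["a", "b"])
    pheno, log = gx.apply_record_filters(table(df))
    assert len(pheno) == 30
    assert log["dropped_small_cg"] == 0 and log["dropped_outliers"] == 0


def test_all_records_removed_fails():
    df = base_records({"a": 5}, ["a"])
    with pytest.raises(ValueError):
        gx.apply_record_filters(table(df), min_cg=10)


# ---------------------------------------------------------------------------
# CG BLUE


def test_balanced_two_group_blue_sum_to_zero():
    df = pd.DataFrame({
        "animal": range(1, 9),
        "y": [10.0] * 4 + [12.0] * 4,
        "cg": ["a"] * 4 + ["b"] * 4,
    })
    est = gx.estimate_cg_effects(table(df), gx.ModelSpec())
    assert est["a"] == pytest.approx(-1.0)
    assert est["b"] == pytest.approx(1.0)


def test_single_cg_estimate_is_zero():
    df = pd.DataFrame({"animal": [1, 2], "y": [3.0, 4.0], "cg": "only"})
    est = gx.estimate_cg_effects(table(df), gx.ModelSpec())
    assert est["only"] == 0.0


def test_blue_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    n = 150
    cg = rng.choice(["a", "b", "c", "d"], n)
    x = rng.standard_normal(n)
    y = 5.0 + 0.8 * x + rng.standard_normal(n)
    df = pd.DataFrame({"animal": range(1, n + 1), "y": y, "cg": cg, "x": x})
    pheno = table(df, covariates=["x"])
    spec = gx.ModelSpec(covariates={"x": 1})
    est = gx.estimate_cg_effects(pheno, spec)
    # oracle: explicit normal equations with sum-to-zero CG coding
    levels = sorted(set(cg))
    D = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        D[:, j] = (cg == lev).astype(float)
    D[cg == levels[-1], :] = -1.0
    X = np.column_stack([np.ones(n), x, D])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    oracle = np.append(beta[2:], -beta[2:].sum())
    assert np.abs(est.to_numpy() - oracle).max() < 1e-9


def test_confounded_cg_fails_with_name():
    df = pd.DataFrame({
        "animal": [1, 2, 3, 4],
        "y": [1.0, 2.0, 3.0, 4.0],
        "cg": ["a", "a", "b", "b"],
        "farm": ["x", "x", "z", "z"],  # identical partition as cg
    })
    with pytest.raises(ValueError, match="[Cc]onfounded"):
        gx.estimate_cg_effects(table(df, factors=["farm"]),
                               gx.ModelSpec(factors=["farm"]))


# ---------------------------------------------------------------------------
# standardization


def test_zscore_example():
    grad = gx.standardize_gradient(pd.Series([1.0, 2.0, 3.0],
                                             index=["a", "b", "c"]))
    np.testing.assert_allclose(grad.theta.to_numpy(), [-1.0, 0.0, 1.0],
                               atol=1e-12)


def test_extreme_cg_dropped_then_restandardized():
    rng = np.random.default_rng(4)
    raw = pd.Series(rng.standard_normal(100),
                    index=[f"cg{i}" for i in range(100)])
    raw["cg0"] = raw.drop("cg0").mean() + 6.0 * raw.drop("cg0").std(ddof=1)
    grad = gx.standardize_gradient(raw)
    assert not bool(grad.table.set_index("cg").loc["cg0", "kept"])
    kept = grad.theta
    assert abs(kept.mean()) < 1e-10
    assert abs(kept.std(ddof=1) - 1.0) < 1e-10


def test_zero_variance_gradient_fails():
    with pytest.raises(ValueError):
        gx.standardize_gradient(pd.Series([2.0, 2.0, 2.0]))


def test_gradient_invariant_to_phenotype_shift():
    rng = np.random.default_rng(5)
    df = base_records({c: 20 for c in "abcd"}, list("abcd"), rng)
    p1 = table(df)
    df2 = df.copy()
    df2["y"] = df2["y"] + 100.0
    g1 = gx.build_gradient(p1, gx.ModelSpec())
    g2 = gx.build_gradient(table(df2), gx.ModelSpec())
    np.testing.assert_allclose(g1.theta.to_numpy(), g2.theta.to_numpy(),
                               atol=1e-10)


def test_gradient_recovers_true_cg_effects():
    """θ̂ correlates with the generative gradient as CGs grow."""
    cfg = gx.SimConfig(n_founders=600, n_generations=1, n_cg=25, seed=6,
                       phenotype_founders=True, n_parities=4,
                       n_auto_snps=5, n_x_snps=0)
    pars = gx.TrueParameters(blocks={}, sigma2_e=1.0, b=1.0, mean=5.0)
    ped = gx.simulate_pedigree(cfg)
    pheno, truth = gx.simulate_phenotypes(ped, pars, cfg)
    grad = gx.build_gradient(pheno, gx.ModelSpec())
    common = grad.theta.index
    r = np.corrcoef(grad.theta.to_numpy(),
                    truth.theta.reindex(common).to_numpy())[0, 1]
    assert r > 0.95


# ---------------------------------------------------------------------------
# model-term selection


def _selection_data(seed, coef):
    rng = np.random.default_rng(seed)
    n = 2000
    cg = rng.choice([f"c{i}" for i in range(8)], n)
    x = rng.standard_normal(n)
    sex = rng.choice(["M", "F"], n)
    y = (3.0 + coef * x + 0.5 * (sex == "F")
         + rng.standard_normal(n))
    df = pd.DataFrame({"animal": range(1, n + 1), "y": y, "cg": cg,
                       "x": x, "sex": sex})
    return table(df, factors=["sex"], covariates=["x"])


def test_null_covariate_eliminated_at_nominal_rate():
    dropped = 0
    reps = 40
    for s in range(reps):
        spec = gx.select_fixed_effects(
            _selection_data(100 + s, 0.0),
            gx.ModelSpec(factors=["sex"], covariates={"x": 1}),
        )
        dropped += "x" not in spec.covariates
    # elimination operates at the 5 % type-I level: expect ~95 %
    assert dropped / reps >= 0.85


def test_strong_covariate_always_retained():
    for s in range(5):
        spec = gx.select_fixed_effects(
            _selection_data(200 + s, 1.0),
            gx.ModelSpec(factors=["sex"], covariates={"x": 1}),
        )
        assert spec.covariates.get("x") == 1
        assert "sex" in spec.factors


def test_all_significant_spec_unchanged():
    spec0 = gx.ModelSpec(factors=["sex"], covariates={"x": 1})
    spec = gx.select_fixed_effects(_selection_data(300, 2.0), spec0)
    assert spec.factors == spec0.factors
    assert spec.covariates == spec0.covariates


def test_quadratic_dropped_before_linear():
    pheno = _selection_data(400, 1.0)
    spec = gx.select_fixed_effects(
        pheno, gx.ModelSpec(factors=["sex"], covariates={"x": 2})
    )
    assert spec.covariates.get("x") == 1  # true model is linear


def test_single_candidate_random_effects_returned():
    only = gx.ModelSpec(random_effects=("a",))
    assert gx.select_random_effects(None, None, [only], None) is only


def test_random_effect_selection_detects_litter_variance():
    """AIC prefers including ce when litters truly vary, and drops it
    (majority of replicates) when they do not."""
    def pick(seed, ce_var):
        cfg = gx.SimConfig(n_founders=30, n_generations=3,
                           litter_size_mean=6, n_matings_per_gen=10,
                           n_cg=10, n_parities=2, seed=seed,
                           n_auto_snps=5, n_x_snps=0)
        blocks = {"a": np.array([[1.0, 0.0], [0.0, 0.1]])}
        if ce_var:
            blocks["ce"] = np.array([[ce_var, 0.0], [0.0, 0.0]])
        pars = gx.TrueParameters(blocks=blocks, sigma2_e=1.0, b=0.5)
        ped = gx.simulate_pedigree(cfg)
        pheno, _ = gx.simulate_phenotypes(ped, pars, cfg)
        spec_a = gx.ModelSpec(factors=["sex"], random_effects=("a",))
        spec_ace = gx.ModelSpec(factors=["sex"], random_effects=("a", "ce"))
        grad = gx.build_gradient(pheno, spec_a)
        pheno = drop_unretained(pheno, grad)
        hinv = pedigree_only_hinv(ped)
        best = gx.select_random_effects(pheno, grad, [spec_a, spec_ace],
                                        hinv, model="RNM1")
        return "ce" in best.random_effects

    with_ce = sum(pick(500 + s, 1.0) for s in range(3))
    without = sum(pick(600 + s, 0.0) for s in range(3))
    assert with_ce >= 2
    assert without <= 1
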