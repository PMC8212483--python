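"""Generator contracts: pedigree structure, Mendelian inheritance,
X-chromosome coding, and the phenotype covariance structure."""

import numpy as np
import pandas as pd
import pytest

import gxenorm as gx
from gxenorm.relmat import Pedigree
from gxenorm.simdata import inject_qtl


def test_founder_only_pedigree():
    ped = gx.simulate_pedigree(gx.SimConfig(n_founders=10, n_generations=1))
    assert len(ped) == 10
    assert (ped.df["sire"] == 0).all() and (ped.df["dam"] == 0).all()


def test_parents_precede_offspring():
    cfg = gx.SimConfig(n_founders=20, n_generations=4, litter_size_mean=4,
                       seed=7)
    ped = gx.simulate_pedigree(cfg)
    pos = {a: i for i, a in enumerate(ped.df["animal"])}
    for _, r in ped.df.iterrows():
        for p in (r["sire"], r["dam"]):
            if p != 0:
                assert pos[p] < pos[r["animal"]]
                sex = ped.df.loc[pos[p], "sex"]
                assert sex == ("M" if p == r["sire"] else "F")


def test_same_seed_reproduces_dataset_exactly():
    cfg = gx.SimConfig(n_founders=16, n_generations=3, litter_size_mean=4,
                       n_cg=6, seed=5, n_auto_snps=30, n_x_snps=2)
    pars = gx.TrueParameters(
        blocks={"a": np.array([[1.0, 0.1], [0.1, 0.2]])}, sigma2_e=1.0
    )
    d1 = gx.simulate_dataset(cfg, pars)
    d2 = gx.simulate_dataset(cfg, pars)
    pd.testing.assert_frame_equal(d1[0].df, d2[0].df)
    np.testing.assert_array_equal(d1[1].dosages, d2[1].dosages)
    pd.testing.assert_frame_equal(d1[2].df, d2[2].df)


def test_impossible_mating_structure_fails():
    # a single mating pair with single-offspring litters soon yields a
    # single-sex generation, which cannot reproduce
    cfg = gx.SimConfig(n_founders=2, n_generations=3, litter_size_mean=1,
                       seed=0)
    with pytest.raises(ValueError, match="impossible mating"):
        gx.simulate_pedigree(cfg)


@pytest.fixture(scope="module")
def full_geno():
    cfg = gx.SimConfig(n_founders=40, n_generations=3, litter_size_mean=5,
                       seed=11, n_auto_snps=60, n_x_snps=8,
                       genotyping_fraction=1.0)
    ped = gx.simulate_pedigree(cfg)
    geno = gx.drop_genotypes(ped, cfg)
    return ped, geno


def test_mendelian_consistency(full_geno):
    """Homozygous parent pairs fully determine autosomal offspring dosage."""
    ped, geno = full_geno
    dose = pd.DataFrame(geno.dosages, index=geno.ids,
                        columns=geno.snps["snp"])
    auto = geno.snps.loc[~geno.is_x(), "snp"]
    checked = 0
    for _, r in ped.df.iterrows():
        if r["sire"] == 0:
            continue
        s, d, o = dose.loc[r["sire"], auto], dose.loc[r["dam"], auto], dose.loc[r["animal"], auto]
        both0 = (s == 0) & (d == 0)
        both2 = (s == 2) & (d == 2)
        assert (o[both0] == 0).all()
        assert (o[both2] == 2).all()
        checked += int(both0.sum() + both2.sum())
    assert checked > 50


def test_male_x_hemizygous_coding(full_geno):
    """Males carry {0,2} X dosages; dam homozygous-alt forces a 2."""
    ped, geno = full_geno
    xsnps = geno.snps.loc[geno.is_x(), "snp"]
    dose = pd.DataFrame(geno.dosages, index=geno.ids,
                        columns=geno.snps["snp"])
    sex = dict(zip(ped.df["animal"], ped.df["sex"]))
    males = [a for a in geno.ids if sex[a] == "M"]
    assert np.isin(dose.loc[males, xsnps].to_numpy(), (0.0, 2.0)).all()
    forced = 0
    for _, r in ped.df.iterrows():
        if r["sire"] == 0 or sex[r["animal"]] != "M":
            continue
        dam2 = dose.loc[r["dam"], xsnps] == 2
        assert (dose.loc[r["animal"], xsnps][dam2] == 2).all()
        forced += int(dam2.sum())
    assert forced > 0


def test_het_cross_segregates_1_2_1():
    """Aa × Aa pooled over SNPs: 1:2:1 within 3 binomial SE."""
    n_off = 1200
    df = pd.DataFrame({
        "animal": np.arange(1, n_off + 3),
        "sire": [0, 0] + [1] * n_off,
        "dam": [0, 0] + [2] * n_off,
        "sex": ["M", "F"] + ["F", "M"] * (n_off // 2),
        "generation": [0, 0] + [1] * n_off,
        "litter": [0, 0] + [1] * n_off,
    })
    ped = Pedigree(df)
    cfg = gx.SimConfig(n_founders=2, n_generations=2, seed=3,
                       n_auto_snps=200, n_x_snps=0,
                       founder_maf_range=(0.5, 0.5), genotyping_fraction=1.0)
    geno = gx.drop_genotypes(ped, cfg)
    dose = pd.DataFrame(geno.dosages, index=geno.ids,
                        columns=geno.snps["snp"])
    het_both = (dose.loc[1] == 1) & (dose.loc[2] == 1)
    snps = het_both.index[het_both]
    assert len(snps) > 20
    off = dose.loc[3:, snps].to_numpy().ravel()
    n = off.size
    for dosage, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
        freq = np.mean(off == dosage)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * se


def test_zero_variance_phenotypes_equal_fixed_part():
    cfg = gx.SimConfig(n_founders=12, n_generations=2, litter_size_mean=4,
                       n_cg=4, seed=9, n_auto_snps=10, n_x_snps=0)
    pars = gx.TrueParameters(blocks={}, sigma2_e=0.0, mean=7.0,
                             sex_effect=1.5, covariate_coef=0.0, b=2.0)
    ped = gx.simulate_pedigree(cfg)
    pheno, truth = gx.simulate_phenotypes(ped, pars, cfg)
    theta = truth.theta.reindex(pheno.df["cg"]).to_numpy()
    sexes = (pheno.df["sex"] == "F").to_numpy()
    expected = 7.0 + 1.5 * sexes + 2.0 * theta
    np.testing.assert_allclose(pheno.df["y"].to_numpy(), expected, atol=1e-12)


def test_total_variance_matches_model():
    """σ²_a0 = 1 on unrelated founders: Var(y) ≈ 1 + σ²_e within 5 %."""
    cfg = gx.SimConfig(n_founders=5000, n_generations=1, n_cg=20, seed=13,
                       phenotype_founders=True, n_parities=1,
                       n_auto_snps=5, n_x_snps=0)
    pars = gx.TrueParameters(blocks={"a": np.array([[1.0, 0.0], [0.0, 0.0]])},
                             sigma2_e=1.0, b=0.0)
    ped = gx.simulate_pedigree(cfg)
    pheno, _ = gx.simulate_phenotypes(ped, pars, cfg)
    assert abs(pheno.df["y"].var(ddof=1) - 2.0) < 0.1


def test_heteroscedastic_variance_recovered_from_residuals():
    """Var(e) = exp(d0 + d1 θ): per-CG log-variance regresses on θ at d1."""
    cfg = gx.SimConfig(n_founders=4000, n_generations=1, n_cg=12, seed=17,
                       phenotype_founders=True, n_parities=1,
                       n_auto_snps=5, n_x_snps=0)
    pars = gx.TrueParameters(blocks={}, sigma2_e=None, d0=0.0, d1=0.5,
                             mean=0.0, b=0.0)
    ped = gx.simulate_pedigree(cfg)
    pheno, truth = gx.simulate_phenotypes(ped, pars, cfg)
    g = pheno.df.groupby("cg")["y"].var(ddof=1)
    th = truth.theta.reindex(g.index).to_numpy()
    slope = np.polyfit(th, np.log(g.to_numpy()), 1)[0]
    assert abs(slope - 0.5) < 0.12


def test_parent_offspring_additive_covariance():
    """Cov(a0_parent, a0_offspring) ≈ σ²_a0 / 2 in a non-inbred design."""
    cfg = gx.SimConfig(n_founders=3000, n_generations=2, litter_size_mean=2,
                       n_matings_per_gen=1200, n_cg=8, seed=19,
                       n_auto_snps=5, n_x_snps=0)
    pars = gx.TrueParameters(blocks={"a": np.array([[1.0, 0.0], [0.0, 0.0]])},
                             sigma2_e=1.0)
    ped = gx.simulate_pedigree(cfg)
    _, truth = gx.simulate_phenotypes(ped, pars, cfg)
    eff = truth.effects.set_index("animal")
    kids = ped.df[ped.df["sire"] != 0]
    cov = np.cov(eff.loc[kids["sire"], "a0"].to_numpy(),
                 eff.loc[kids["animal"], "a0"].to_numpy())[0, 1]
    assert abs(cov - 0.5) < 0.08


def test_founder_block_covariance_converges():
    """Sampled (a0, a1) of founders reproduce the generative block."""
    B = np.array([[1.0, 0.35], [0.35, 0.4]])
    cfg = gx.SimConfig(n_founders=20000, n_generations=1, n_cg=5, seed=23,
                       phenotype_founders=True, n_auto_snps=5, n_x_snps=0)
    pars = gx.TrueParameters(blocks={"a": B}, sigma2_e=1.0)
    ped = gx.simulate_pedigree(cfg)
    _, truth = gx.simulate_phenotypes(ped, pars, cfg)
    emp = np.cov(truth.effects["a0"], truth.effects["a1"])
    # 3 Monte-Carlo SE per entry; Var(cov) ≈ (B_ii B_jj + B_ij²)/n
    n = cfg.n_founders
    for i in range(2):
        for j in range(2):
            se = np.sqrt((B[i, i] * B[j, j] + B[i, j] ** 2) / n)
            assert abs(emp[i, j] - B[i, j]) < 3 * se


def test_non_psd_block_rejected_by_name():
    cfg = gx.SimConfig(n_founders=10, n_generations=2, seed=1,
                       n_auto_snps=5, n_x_snps=0)
    bad = gx.TrueParameters(blocks={"pe": np.array([[1.0, 2.0], [2.0, 1.0]])})
    ped = gx.simulate_pedigree(cfg)
    with pytest.raises(ValueError, match="pe"):
        gx.simulate_phenotypes(ped, bad, cfg)


def test_inject_qtl_adds_slope_signal(full_geno):
    ped, geno = full_geno
    cfg = gx.SimConfig(n_founders=40, n_generations=3, litter_size_mean=5,
                       seed=11, n_auto_snps=60, n_x_snps=8,
                       genotyping_fraction=1.0)
    pars = gx.TrueParameters(blocks={}, sigma2_e=0.0, mean=0.0, b=0.0)
    pheno, truth = gx.simulate_phenotypes(ped, pars, cfg)
    snp = geno.snps["snp"].iloc[0]
    boosted = inject_qtl(pheno, truth, geno, snp, slope_effect=1.0)
    z = pd.Series(geno.centered()[:, 0], index=geno.ids)
    theta = truth.theta.reindex(pheno.df["cg"]).to_numpy()
    expect = z.reindex(pheno.df["animal"]).to_numpy() * theta
    np.testing.assert_allclose(
        boosted.df["y"].to_numpy() - pheno.df["y"].to_numpy(), expect,
        atol=1e-12,
    )
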