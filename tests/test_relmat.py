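"""Relationship matrices against independent oracles, and genotype QC."""

import numpy as np
import pandas as pd
import pytest

import gxenorm as gx
from gxenorm.relmat import Pedigree, PedigreeError


def ped_from_rows(rows):
    return Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex"]))


# independent oracle: recursive coancestry (kinship), A_ij = 2 f_ij
def kinship_oracle(df):
    pos = {a: i for i, a in enumerate(df["animal"])}
    sire = [pos.get(s, -1) for s in df["sire"]]
    dam = [pos.get(d, -1) for d in df["dam"]]
    memo = {}

    def f(a, b):
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        if (a, b) in memo:
            return memo[(a, b)]
        if a == b:
            v = 0.5 * (1.0 + f(sire[a], dam[a]))
        else:
            v = 0.5 * (f(a, sire[b]) + f(a, dam[b]))
        memo[(a, b)] = v
        return v

    n = len(df)
    return np.array([[2.0 * f(i, j) for j in range(n)] for i in range(n)])


def test_tabular_base_case():
    ped = ped_from_rows([(1, 0, 0, "M"), (2, 0, 0, "F"), (3, 1, 2, "F")])
    A, F = gx.build_A(ped)
    assert A.loc(1, 3) == pytest.approx(0.5)
    assert A.loc(3, 3) == pytest.approx(1.0)
    assert F[2] == 0.0


def test_sire_daughter_mating_inbreeding():
    ped = ped_from_rows(
        [(1, 0, 0, "M"), (2, 0, 0, "F"), (3, 1, 2, "F"), (4, 1, 3, "M")]
    )
    A, F = gx.build_A(ped)
    assert F[3] == pytest.approx(0.25)
    assert A.loc(4, 4) == pytest.approx(1.25)
    assert ped.inbreeding()[3] == pytest.approx(0.25)


def test_tabular_A_matches_coancestry_oracle():
    cfg = gx.SimConfig(n_founders=8, n_generations=3, litter_size_mean=3,
                       seed=31)
    ped = gx.simulate_pedigree(cfg)
    ped.df = ped.df.head(25).reset_index(drop=True)
    ped = Pedigree(ped.df[["animal", "sire", "dam", "sex"]].copy())
    A, F = gx.build_A(ped)
    oracle = kinship_oracle(ped.df)
    assert np.abs(A.to_dense() - oracle).max() < 1e-12
    # diag(A) = 1 + F with F from the same independent recursion
    assert np.abs(np.diag(oracle) - 1.0 - F).max() < 1e-12
    assert np.abs(ped.inbreeding() - F).max() < 1e-12


def test_A_psd_and_inverse_consistency():
    cfg = gx.SimConfig(n_founders=12, n_generations=4, litter_size_mean=3,
                       seed=37)
    ped = gx.simulate_pedigree(cfg)
    A, _ = gx.build_A(ped)
    Ad = A.to_dense()
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.standard_normal(len(ped))
        assert x @ Ad @ x >= -1e-10
    Ainv = gx.build_A_inverse(ped).to_dense()
    assert np.abs(Ainv - np.linalg.inv(Ad)).max() < 1e-8
    assert np.abs(Ainv - Ainv.T).max() < 1e-12


def test_cyclic_pedigree_rejected():
    df = pd.DataFrame(
        {"animal": [1, 2], "sire": [2, 1], "dam": [0, 0], "sex": ["M", "M"]}
    )
    with pytest.raises(PedigreeError, match="cycle"):
        Pedigree(df)


# ---------------------------------------------------------------------------
# genotype QC


def geno_with(dosage_cols, sexes=None, chroms=None):
    n, m = dosage_cols.shape
    snps = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else ["1"] * m,
        "pos": np.arange(1, m + 1) * 100,
    })
    return gx.GenotypeMatrix(np.arange(1, n + 1), snps, dosage_cols,
                             sexes=sexes)


def test_qc_thresholds_match_rules():
    rng = np.random.default_rng(2)
    n, m_filler = 200, 20
    p = 0.4
    base = rng.choice(
        [0.0, 1.0, 2.0], size=(n, 4 + m_filler),
        p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
    )
    # col 0: MAF 0.005 → removed
    base[:, 0] = 0.0
    base[:2, 0] = 1.0
    # col 1: call rate 0.89 → removed (animals keep call rate ≥ 0.95)
    base[: int(n * 0.11) + 1, 1] = np.nan
    # col 2 stays Hardy-Weinberg-consistent → kept
    # col 3: het diff ≥ 0.15 → removed (all heterozygous)
    base[:, 3] = 1.0
    geno = geno_with(base)
    kept, rep = gx.qc_genotypes(geno)
    mtr = rep.snp_metrics.set_index("snp")
    assert mtr.loc["s0", "reason"] == "maf"
    assert mtr.loc["s1", "reason"] == "call_rate"
    assert bool(mtr.loc["s2", "kept"])
    assert mtr.loc["s3", "reason"] == "het_diff"
    assert rep.n_removed_snps + int(mtr["kept"].sum()) == 4 + m_filler


def test_qc_het_diff_boundary():
    rng = np.random.default_rng(3)
    n = 10000
    p = 0.5
    # expected het 0.5; build columns with observed het 0.36 (kept: diff .14)
    # and 0.66 (removed: diff .16)
    def col(obs_het):
        homs = n - int(n * obs_het)
        c = np.array([1.0] * int(n * obs_het)
                     + [0.0] * (homs // 2) + [2.0] * (homs - homs // 2))
        return c
    d = np.column_stack([col(0.36), col(0.66)])
    kept, rep = gx.qc_genotypes(geno_with(d))
    m = rep.snp_metrics.set_index("snp")
    assert bool(m.loc["s0", "kept"])
    assert m.loc["s1", "reason"] == "het_diff"


def test_qc_idempotent():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.5, 30)
    d = rng.binomial(2, p, size=(300, 30)).astype(float)
    g1, _ = gx.qc_genotypes(geno_with(d))
    g2, rep2 = gx.qc_genotypes(g1)
    assert rep2.n_removed_snps == 0
    assert g2.n_snps == g1.n_snps


def test_qc_all_removed_fails():
    d = np.ones((50, 2))  # monomorphic heterozygotes: removed by het rule
    with pytest.raises(ValueError, match="every SNP"):
        gx.qc_genotypes(geno_with(d))


# ---------------------------------------------------------------------------
# genomic relationship matrix


def test_G_single_snp_closed_form():
    d = np.array([[0.0], [1.0], [2.0]])
    G = gx.build_G(geno_with(d)).to_dense()
    np.testing.assert_allclose(
        G, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
    )


def test_G_rows_center_to_zero():
    rng = np.random.default_rng(7)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 50), size=(40, 50)).astype(float)
    G = gx.build_G(geno_with(d)).to_dense()
    assert np.abs(G.mean(axis=1)).max() < 1e-10


def test_G_matches_bruteforce_loops():
    rng = np.random.default_rng(9)
    d = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(20, 200)).astype(float)
    geno = geno_with(d)
    G = gx.build_G(geno).to_dense()
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * sum(pk * (1 - pk) for pk in p)
    Z = d - 2.0 * p
    brute = np.empty((20, 20))
    for i in range(20):
        for j in range(20):
            brute[i, j] = sum(Z[i, k] * Z[j, k] for k in range(200)) / denom
    assert np.abs(G - brute).max() < 1e-10


def test_G_monomorphic_only_fails():
    d = np.zeros((5, 3))
    with pytest.raises(ValueError, match="monomorphic"):
        gx.build_G(geno_with(d))


# ---------------------------------------------------------------------------
# hybrid inverse


def test_Hinv_reduces_to_Ainv_without_genotypes():
    cfg = gx.SimConfig(n_founders=6, n_generations=2, litter_size_mean=3,
                       seed=41)
    ped = gx.simulate_pedigree(cfg)
    ainv = gx.build_A_inverse(ped)
    H = gx.build_Hinv(ainv, None, None, [])
    assert np.array_equal(H.to_dense(), ainv.to_dense())


def test_Hinv_correction_cancels_when_G_equals_A22():
    cfg = gx.SimConfig(n_founders=6, n_generations=3, litter_size_mean=3,
                       seed=43)
    ped = gx.simulate_pedigree(cfg)
    A, _ = gx.build_A(ped)
    ainv = gx.build_A_inverse(ped)
    gen_ids = ped.animals[-4:]
    a22 = A.subset(gen_ids)
    a22inv = gx.invert_relationship(a22, "A22inv")
    g_inv = gx.RelationshipMatrix(gen_ids, a22inv.to_dense().copy(), "Ginv")
    H = gx.build_Hinv(ainv, a22inv, g_inv, gen_ids)
    assert np.abs(H.to_dense() - ainv.to_dense()).max() < 1e-10


def test_Hinv_matches_direct_H_oracle():
    """Invert the joint H built from the conditional-Gaussian construction."""
    ped = ped_from_rows(
        [(1, 0, 0, "M"), (2, 0, 0, "F"), (3, 1, 2, "M"), (4, 1, 2, "F"),
         (5, 3, 4, "M"), (6, 3, 4, "F")]
    )
    A, _ = gx.build_A(ped)
    ainv = gx.build_A_inverse(ped)
    gen_ids = np.array([4, 5, 6])
    rng = np.random.default_rng(11)
    d = rng.binomial(2, rng.uniform(0.2, 0.5, 80), size=(3, 80)).astype(float)
    geno = gx.GenotypeMatrix(
        gen_ids,
        pd.DataFrame({"snp": [f"s{j}" for j in range(80)], "chrom": "1",
                      "pos": np.arange(80) * 10 + 1}),
        d,
    )
    a22 = A.subset(gen_ids)
    G = gx.build_G(geno, blend_a22=a22, blend_weight=0.1)
    Hinv = gx.build_Hinv(
        ainv, gx.invert_relationship(a22, "A22inv"),
        gx.invert_relationship(G, "Ginv"), gen_ids,
    )
    # direct H: replace the genotyped block, propagate via A12 A22⁻¹
    ids = list(ped.animals)
    gpos = [ids.index(a) for a in gen_ids]
    npos = [i for i in range(len(ids)) if i not in gpos]
    Ad = A.to_dense()
    A11, A12 = Ad[np.ix_(npos, npos)], Ad[np.ix_(npos, gpos)]
    A22d, Gd = Ad[np.ix_(gpos, gpos)], G.to_dense()
    T = A12 @ np.linalg.inv(A22d)
    H = np.zeros_like(Ad)
    H[np.ix_(npos, npos)] = A11 + T @ (Gd - A22d) @ T.T
    H[np.ix_(npos, gpos)] = T @ Gd
    H[np.ix_(gpos, npos)] = (T @ Gd).T
    H[np.ix_(gpos, gpos)] = Gd
    assert np.abs(Hinv.to_dense() - np.linalg.inv(H)).max() < 1e-8
    assert np.abs(Hinv.to_dense() - Hinv.to_dense().T).max() < 1e-12


def test_singular_unblended_G_instructs_blending():
    # one SNP across 3 animals gives a rank-deficient G
    d = np.array([[0.0], [1.0], [2.0]])
    G = gx.build_G(geno_with(d))
    with pytest.raises(ValueError, match="blend"):
        gx.invert_relationship(G)
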