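"""Synthetic pedigree, genotype and phenotype generator.

Generates data with exactly the covariance structure the reaction-norm
analysis assumes: a multi-generation pedigree, gene-dropped genotypes on
autosomes and the X chromosome (male dosages on the {0, 2} hemizygote
scale), contemporary groups of heterogeneous size whose standardized
true effects form the environmental gradient, and phenotypes

    y = x'β + b·θ + (a0 + a1·θ) + (pe0 + pe1·θ) + (ce0 + ce1·θ) + e

with pedigree-correlated additive intercept/slope pairs, i.i.d. animal
permanent-environment and birth-litter effects, and a residual that is
either homogeneous or exponentially heteroscedastic, Var(e) =
exp(d0 + d1·θ).  True effects are returned alongside the phenotypes so
recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .envgrad import PhenotypeTable
from .relmat import GenotypeMatrix, Pedigree

__all__ = [
    "SimConfig",
    "TrueParameters",
    "SimTruth",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    n_founders: int = 100
    n_generations: int = 3
    litter_size_mean: int = 8
    n_matings_per_gen: int | None = None  # None: mate every available dam
    n_cg: int = 30
    cg_size_range: tuple[int, int] = (10, 60)
    n_auto_snps: int = 480
    n_x_snps: int = 20  # ~4 % of the panel, as on commercial pig chips
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_fraction: float = 0.6
    n_parities: int = 2  # phenotype records per animal, each in its own CG
    phenotype_founders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 < self.genotyping_fraction <= 1.0:
            raise ValueError("genotyping_fraction must be in (0, 1]")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")


@dataclass
class TrueParameters:
    """Generative (co)variance blocks, residual model and fixed effects."""

    blocks: dict = field(default_factory=dict)  # {"a"|"pe"|"ce": 2×2 array}
    sigma2_e: float | None = 1.0  # homogeneous residual variance
    d0: float | None = None  # heteroscedastic residual: Var(e) = exp(d0+d1·θ)
    d1: float | None = None
    mean: float = 10.0
    sex_effect: float = 0.0  # added for females
    covariate_coef: float = 0.0  # slope on the simulated "age" covariate
    b: float = 0.5  # overall fixed regression on the gradient

    @property
    def heteroscedastic(self) -> bool:
        return self.d0 is not None

    def residual_variance(self, theta: np.ndarray) -> np.ndarray:
        if self.heteroscedastic:
            return np.exp(self.d0 + self.d1 * np.asarray(theta))
        return np.full(np.shape(theta), float(self.sigma2_e))

    def validate(self) -> None:
        for name, B in self.blocks.items():
            B = np.asarray(B, dtype=float)
            if B.shape != (2, 2) or abs(B[0, 1] - B[1, 0]) > 1e-12:
                raise ValueError(f"block {name!r} must be symmetric 2×2")
            ev = np.linalg.eigvalsh(B)
            if ev[0] < -1e-10:
                raise ValueError(
                    f"covariance block {name!r} is not positive semi-definite"
                )
        if not self.heteroscedastic and (self.sigma2_e is None or self.sigma2_e < 0):
            raise ValueError("sigma2_e must be non-negative")


@dataclass
class SimTruth:
    """Per-animal true effects and generative parameters, kept for tests."""

    params: TrueParameters
    effects: pd.DataFrame  # animal, a0, a1, pe0, pe1
    litter_effects: pd.DataFrame  # litter, ce0, ce1
    theta: pd.Series  # true standardized gradient per CG


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random discrete-generation pedigree with litters.

    Founders have unknown parents; each later generation mates a random
    sire (with replacement) to each selected dam, producing a litter of
    ``1 + Poisson(litter_size_mean − 1)`` full sibs.  Animal ids are
    assigned in birth order, so the pedigree is topologically ordered by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    next_id = 1
    next_litter = 1
    sexes = rng.permuted(
        np.array(["M", "F"])[np.arange(config.n_founders) % 2]
    )
    generation = {}
    for _ in range(config.n_founders):
        records.append((next_id, 0, 0, sexes[next_id - 1], 0, 0))
        generation[next_id] = 0
        next_id += 1
    prev = [r[0] for r in records]
    for gen in range(1, config.n_generations):
        males = [a for a in prev if records[a - 1][3] == "M"]
        females = [a for a in prev if records[a - 1][3] == "F"]
        if not males or not females:
            raise ValueError(
                f"impossible mating structure: generation {gen - 1} has "
                f"{len(males)} males and {len(females)} females"
            )
        n_mat = config.n_matings_per_gen or len(females)
        dams = rng.choice(females, size=min(n_mat, len(females)), replace=False)
        new = []
        for dam in dams:
            sire = int(rng.choice(males))
            size = 1 + rng.poisson(max(config.litter_size_mean - 1, 0))
            litter = next_litter
            next_litter += 1
            for _ in range(size):
                sex = "M" if rng.random() < 0.5 else "F"
                records.append((next_id, sire, int(dam), sex, gen, litter))
                generation[next_id] = gen
                new.append(next_id)
                next_id += 1
        prev = new
    df = pd.DataFrame(
        records, columns=["animal", "sire", "dam", "sex", "generation", "litter"]
    )
    return Pedigree(df)


# ---------------------------------------------------------------------------
# genotypes


def drop_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop founder alleles through the pedigree.

    Autosomal SNPs segregate Mendelian: one random allele from each
    parent.  X-linked SNPs: a daughter receives her sire's only X plus a
    random maternal X; a son receives a random maternal X, coded {0, 2}.
    Only a ``genotyping_fraction`` subset of animals — biased toward
    recent generations — is returned as genotyped.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_auto, n_x = config.n_auto_snps, config.n_x_snps
    m = n_auto + n_x
    lo, hi = config.founder_maf_range
    p0 = rng.uniform(lo, hi, size=m)
    is_x = np.zeros(m, dtype=bool)
    is_x[n_auto:] = True

    sire, dam = pedigree.parent_indices()
    sex = pedigree.df["sex"].to_numpy()
    n = len(pedigree)
    # paternal / maternal allele per animal per SNP
    pat = np.zeros((n, m), dtype=np.int8)
    mat = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            pat[i] = rng.random(m) < p0
            mat[i] = rng.random(m) < p0
            if sex[i] == "M":
                pat[i, is_x] = mat[i, is_x]  # single X, stored twice
            continue
        # maternal gamete: random pick from the dam's two alleles
        pick = rng.random(m) < 0.5
        mat[i] = np.where(pick, pat[d], mat[d])
        # paternal gamete
        pickp = rng.random(m) < 0.5
        pat[i] = np.where(pickp, pat[s], mat[s])
        if is_x.any():
            if sex[i] == "F":
                pat[i, is_x] = mat[s, is_x]  # sire's only X
            else:
                pat[i, is_x] = mat[i, is_x]  # hemizygous: duplicate maternal X
    dosage = (pat + mat).astype(float)

    # genotyped subset biased toward recent generations
    gen = (
        pedigree.df["generation"].to_numpy()
        if "generation" in pedigree.df.columns
        else np.zeros(n)
    )
    w = (1.0 + gen) ** 2
    k = max(2, int(round(config.genotyping_fraction * n)))
    chosen = rng.choice(n, size=min(k, n), replace=False, p=w / w.sum())
    chosen.sort()

    chrom = np.where(is_x, "X", (np.arange(m) % 18 + 1).astype(str))
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = np.sort(rng.integers(1, 150_000_000, size=sel.sum()))
    snps = pd.DataFrame(
        {"snp": [f"snp{j + 1}" for j in range(m)], "chrom": chrom, "pos": pos}
    )
    # order by chromosome (1..18 then X), then position
    chrom_rank = np.where(is_x, 99, (np.arange(m) % 18 + 1))
    order = np.lexsort((pos, chrom_rank))
    snps = snps.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(
        pedigree.animals[chosen],
        snps,
        dosage[np.ix_(chosen, order)],
        sexes=sex[chosen],
    )


# ---------------------------------------------------------------------------
# phenotypes


def _draw_block_effects(rng, B: np.ndarray, n: int) -> np.ndarray:
    """n i.i.d. draws from N(0, B) for a possibly singular 2×2 block."""
    w, V = np.linalg.eigh(np.asarray(B, dtype=float))
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    return rng.standard_normal((n, 2)) @ L.T


def _pedigree_effects(pedigree: Pedigree, B, rng) -> np.ndarray:
    """(a0, a1) pairs with Cov(a_i, a_j) = A_ij · B via gene-flow recursion."""
    sire, dam = pedigree.parent_indices()
    F = pedigree.inbreeding()
    n = len(pedigree)
    w, V = np.linalg.eigh(np.asarray(B, dtype=float))
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, 2))
    a = np.zeros((n, 2))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            mu = 0.5 * (a[s] + a[d])
            msv = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mu = 0.5 * a[p]
            msv = 0.75 - 0.25 * F[p]
        else:
            mu = 0.0
            msv = 1.0
        a[i] = mu + np.sqrt(msv) * (z[i] @ L.T)
    return a


def simulate_phenotypes(
    pedigree: Pedigree,
    params: TrueParameters,
    config: SimConfig,
) -> tuple[PhenotypeTable, SimTruth]:
    """Phenotypes under the reaction-norm generative model.

    Every non-founder (founders too, if configured) receives
    ``n_parities`` records, each assigned to a contemporary group drawn
    with heterogeneous weights.  The litter effect is shared by full
    sibs (birth litter).
    """
    params.validate()
    rng = np.random.default_rng(config.seed + 2)
    n = len(pedigree)
    zero = np.zeros((2, 2))

    a = (
        _pedigree_effects(pedigree, params.blocks["a"], rng)
        if "a" in params.blocks
        else np.zeros((n, 2))
    )
    pe = _draw_block_effects(rng, params.blocks.get("pe", zero), n)

    if "litter" in pedigree.df.columns:
        litters = pedigree.df["litter"].to_numpy()
    else:
        litters = np.arange(1, n + 1)
    ulit = np.unique(litters)
    ce = _draw_block_effects(rng, params.blocks.get("ce", zero), len(ulit))
    lit_pos = {l: i for i, l in enumerate(ulit)}

    # true gradient: drawn standard normal, then standardized (mean 0, SD 1)
    theta_raw = rng.standard_normal(config.n_cg)
    theta = (theta_raw - theta_raw.mean()) / theta_raw.std(ddof=1)
    cg_w = rng.uniform(*config.cg_size_range, size=config.n_cg)
    cg_w /= cg_w.sum()

    founder = (pedigree.df["sire"].to_numpy() == 0) & (
        pedigree.df["dam"].to_numpy() == 0
    )
    pheno_idx = np.arange(n) if config.phenotype_founders else np.where(~founder)[0]
    if pheno_idx.size == 0:
        raise ValueError("no animals to phenotype (founder-only pedigree)")

    rows = []
    sexes = pedigree.df["sex"].to_numpy()
    animals = pedigree.animals
    for i in pheno_idx:
        for parity in range(1, config.n_parities + 1):
            cg = int(rng.choice(config.n_cg, p=cg_w))
            t = theta[cg]
            x_age = rng.standard_normal()
            var_e = float(params.residual_variance(t))
            e = rng.standard_normal() * np.sqrt(var_e)
            li = lit_pos[litters[i]]
            y = (
                params.mean
                + (params.sex_effect if sexes[i] == "F" else 0.0)
                + params.covariate_coef * x_age
                + params.b * t
                + a[i, 0] + a[i, 1] * t
                + pe[i, 0] + pe[i, 1] * t
                + ce[li, 0] + ce[li, 1] * t
                + e
            )
            rows.append(
                (animals[i], y, f"cg{cg + 1}", sexes[i], x_age, litters[i], parity)
            )
    df = pd.DataFrame(
        rows, columns=["animal", "y", "cg", "sex", "age", "litter", "parity"]
    )
    pheno = PhenotypeTable(
        df, factors=["sex"], covariates=["age"], trait="simulated trait"
    )
    truth = SimTruth(
        params=params,
        effects=pd.DataFrame(
            {
                "animal": animals,
                "a0": a[:, 0],
                "a1": a[:, 1],
                "pe0": pe[:, 0],
                "pe1": pe[:, 1],
            }
        ),
        litter_effects=pd.DataFrame(
            {"litter": ulit, "ce0": ce[:, 0], "ce1": ce[:, 1]}
        ),
        theta=pd.Series(theta, index=[f"cg{j + 1}" for j in range(config.n_cg)]),
    )
    return pheno, truth


def inject_qtl(
    pheno: PhenotypeTable,
    truth: SimTruth,
    geno: GenotypeMatrix,
    snp: str,
    intercept_effect: float = 0.0,
    slope_effect: float = 0.0,
) -> PhenotypeTable:
    """Add a single-SNP effect to intercept and/or slope of every record.

    The centred dosage of ``snp`` enters the phenotype as an extra
    additive contribution ``z_j (β0 + β1 θ)``, creating a QTL whose
    slope component makes it environment-sensitive.  Every phenotyped
    animal must be genotyped (simulate with ``genotyping_fraction=1``).
    """
    j = geno.snps.index[geno.snps["snp"] == snp]
    if len(j) != 1:
        raise ValueError(f"SNP {snp!r} not in the genotype matrix")
    z = pd.Series(geno.centered()[:, j[0]], index=geno.ids)
    zj = z.reindex(pheno.df["animal"])
    if zj.isna().any():
        raise ValueError("all phenotyped animals must be genotyped for a QTL")
    theta = truth.theta.reindex(pheno.df["cg"]).to_numpy()
    df = pheno.df.copy()
    df["y"] = (
        df["y"].to_numpy()
        + zj.to_numpy() * (intercept_effect + slope_effect * theta)
    )
    return replace(pheno, df=df)


def simulate_dataset(
    config: SimConfig, params: TrueParameters
) -> tuple[Pedigree, GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Pedigree + genotypes + phenotypes in one deterministic call."""
    ped = simulate_pedigree(config)
    geno = drop_genotypes(ped, config)
    pheno, truth = simulate_phenotypes(ped, params, config)
    return ped, geno, pheno, truth
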