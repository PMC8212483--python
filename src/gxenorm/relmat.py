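"""Pedigree, genomic and hybrid relationship matrices, plus genotype QC.

The single-step machinery rests on three matrices:

* ``A``   — the numerator relationship matrix from the pedigree (tabular
  method), whose diagonal is ``1 + F`` with ``F`` the inbreeding
  coefficient;
* ``G``   — the genomic relationship matrix from centred SNP dosages
  (VanRaden method 1), optionally blended with the pedigree block
  ``A22`` to guarantee invertibility;
* ``H⁻¹`` — the hybrid inverse used in the mixed-model equations,
  ``H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]`` on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "QCReport",
    "RelationshipMatrix",
    "qc_genotypes",
    "build_A",
    "build_A_inverse",
    "build_G",
    "build_Hinv",
]

UNKNOWN = 0  # parent code for "unknown" in integer-coded pedigrees


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree with integer animal ids.

    ``sire``/``dam`` use 0 for unknown parents.  Construction validates
    that the pedigree is acyclic, that sires are male and dams female,
    and reorders records so parents always precede offspring.
    """

    df: pd.DataFrame  # columns: animal, sire, dam, sex; optional: generation

    def __post_init__(self) -> None:
        req = {"animal", "sire", "dam", "sex"}
        missing = req - set(self.df.columns)
        if missing:
            raise PedigreeError(f"pedigree missing columns: {sorted(missing)}")
        df = self.df.copy()
        for c in ("animal", "sire", "dam"):
            df[c] = df[c].fillna(UNKNOWN).astype(np.int64)
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].tolist()
            raise PedigreeError(f"duplicated animal ids: {dup[:10]}")
        if (df["animal"] == UNKNOWN).any():
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        self.df = self._toposort(df)
        self._pos = {a: i for i, a in enumerate(self.df["animal"])}
        self._validate_sexes()
        self._f: np.ndarray | None = None

    @staticmethod
    def _toposort(df: pd.DataFrame) -> pd.DataFrame:
        ids = set(df["animal"])
        for c in ("sire", "dam"):
            bad = set(df[c]) - ids - {UNKNOWN}
            if bad:
                raise PedigreeError(f"{c} ids not in pedigree: {sorted(bad)[:10]}")
        row = {a: i for i, a in enumerate(df["animal"])}
        sire = df["sire"].to_numpy()
        dam = df["dam"].to_numpy()
        n = len(df)
        state = np.zeros(n, np.int8)  # 0 unvisited, 1 on stack, 2 done
        order: list[int] = []
        for start in range(n):
            if state[start]:
                continue
            stack = [(start, False)]
            while stack:
                i, processed = stack.pop()
                if processed:
                    state[i] = 2
                    order.append(i)
                    continue
                if state[i] == 2:
                    continue
                if state[i] == 1:
                    raise PedigreeError(
                        f"pedigree cycle involving animal {df['animal'].iat[i]}"
                    )
                state[i] = 1
                stack.append((i, True))
                for p in (sire[i], dam[i]):
                    if p != UNKNOWN:
                        j = row[p]
                        if state[j] == 1:
                            raise PedigreeError(
                                f"pedigree cycle involving animal {p}"
                            )
                        if state[j] == 0:
                            stack.append((j, False))
        return df.iloc[order].reset_index(drop=True)

    def _validate_sexes(self) -> None:
        sex = dict(zip(self.df["animal"], self.df["sex"]))
        bad_s = [s for s in self.df["sire"] if s != UNKNOWN and sex[s] != "M"]
        bad_d = [d for d in self.df["dam"] if d != UNKNOWN and sex[d] != "F"]
        if bad_s or bad_d:
            raise PedigreeError(
                f"sires that are not male: {sorted(set(bad_s))[:5]}; "
                f"dams that are not female: {sorted(set(bad_d))[:5]}"
            )

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy()

    def position(self, animal_ids) -> np.ndarray:
        try:
            return np.array([self._pos[a] for a in np.asarray(animal_ids)])
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]} not in pedigree") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based parent row indices, -1 for unknown."""
        out = []
        for c in ("sire", "dam"):
            p = self.df[c].to_numpy()
            idx = np.array([self._pos[v] if v != UNKNOWN else -1 for v in p])
            out.append(idx)
        return out[0], out[1]

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen & Luo recursion."""
        if self._f is None:
            self._f = _meuwissen_luo(*self.parent_indices())
        return self._f

    def offspring_counts(self) -> pd.Series:
        cnt = pd.concat([self.df["sire"], self.df["dam"]]).value_counts()
        cnt = cnt.drop(UNKNOWN, errors="ignore")
        return cnt.reindex(self.df["animal"], fill_value=0)


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = len(sire)
    f = np.zeros(n)
    memo: dict = {}
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            continue
        # F_i = kinship of the parents, by memoised coancestry recursion
        f[i] = _kinship(s, d, sire, dam, memo)
    return f


def _kinship(a: int, b: int, sire, dam, memo) -> float:
    if a < 0 or b < 0:
        return 0.0
    if a > b:
        a, b = b, a
    key = (a, b)
    if key in memo:
        return memo[key]
    if a == b:
        val = 0.5 * (1.0 + _kinship(sire[a], dam[a], sire, dam, memo))
    else:
        # b is the later-born animal (topological order ensures index order)
        val = 0.5 * (
            _kinship(a, sire[b], sire, dam, memo)
            + _kinship(a, dam[b], sire, dam, memo)
        )
    memo[key] = val
    return val


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with an animal-id index."""

    ids: np.ndarray
    values: np.ndarray  # dense (n, n) or scipy sparse
    kind: str  # A, A22, G, Ainv, A22inv, Ginv, Hinv

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def to_dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return self.values.toarray()
        return self.values

    def subset(self, ids) -> "RelationshipMatrix":
        idx = np.array([self._pos[a] for a in ids])
        dense = self.to_dense()
        return RelationshipMatrix(np.asarray(ids), dense[np.ix_(idx, idx)], self.kind)

    def loc(self, a, b) -> float:
        return float(self.to_dense()[self._pos[a], self._pos[b]])


def build_A(pedigree: Pedigree) -> tuple[RelationshipMatrix, np.ndarray]:
    """Numerator relationship matrix by the tabular method.

    Returns ``(A, F)`` where ``diag(A) = 1 + F``.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        if i == 0:
            continue
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    F = np.diag(A) - 1.0
    return RelationshipMatrix(pedigree.animals, A, "A"), F


def build_A_inverse(pedigree: Pedigree, as_sparse: bool = False) -> RelationshipMatrix:
    """A⁻¹ by Henderson's rules with inbreeding.

    Mendelian sampling variances use the parents' inbreeding
    coefficients; unknown parents contribute the usual 3/4 or 1 terms.
    """
    sire, dam = pedigree.parent_indices()
    F = pedigree.inbreeding()
    n = len(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            m = 0.75 - 0.25 * F[s]
        elif d >= 0:
            m = 0.75 - 0.25 * F[d]
        else:
            m = 1.0
        b = 1.0 / m
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * b)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    values = Ainv if as_sparse else Ainv.toarray()
    return RelationshipMatrix(pedigree.animals, values, "Ainv")


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenotypeMatrix:
    """Allele dosages (animals × SNPs) with a SNP map.

    Dosages are 0/1/2 with NaN for missing calls.  Male X-chromosome
    genotypes are hemizygous and coded on the {0, 2} scale so that the
    single allele contributes like a homozygote.
    """

    ids: np.ndarray
    snps: pd.DataFrame  # columns: snp, chrom (str, "1".."18" or "X"), pos
    dosages: np.ndarray  # float array, NaN = missing
    sexes: np.ndarray | None = None  # "M"/"F" aligned with ids, for X QC

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snps)):
            raise ValueError("dosage shape does not match ids × snps")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing")
        self.snps = self.snps.reset_index(drop=True)
        pos = self.snps.groupby("chrom", sort=False)["pos"]
        if (self.snps["pos"] < 0).any() or not pos.apply(
            lambda s: s.is_monotonic_increasing
        ).all():
            raise ValueError("SNP positions must be non-negative and sorted "
                             "within chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_frequencies(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0

    def is_x(self) -> np.ndarray:
        return (self.snps["chrom"].astype(str) == "X").to_numpy()

    def exclude_x(self) -> "GenotypeMatrix":
        keep = ~self.is_x()
        return GenotypeMatrix(
            self.ids, self.snps.loc[keep], self.dosages[:, keep], self.sexes
        )

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Column-centred dosages; missing values imputed at the mean."""
        p = self.allele_frequencies() if freqs is None else np.asarray(freqs)
        Z = self.dosages - 2.0 * p
        return np.where(np.isnan(Z), 0.0, Z)


@dataclass
class QCReport:
    snp_metrics: pd.DataFrame  # snp, call_rate, maf, het_diff, kept, reason
    animal_metrics: pd.DataFrame  # animal, call_rate, kept
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed_snps(self) -> int:
        return int((~self.snp_metrics["kept"]).sum())


def qc_genotypes(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    het_diff_max: float = 0.15,
    animal_call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs/animals failing call-rate, MAF and heterozygosity checks.

    A SNP is dropped when its call rate is not above ``call_rate_min``,
    its minor allele frequency not above ``maf_min``, or the absolute
    difference between observed and expected (2p(1−p)) heterozygote
    frequencies is not below ``het_diff_max``.  For X-linked SNPs the
    heterozygosity comparison uses females only, since hemizygous males
    are never heterozygous under the {0, 2} coding.
    """
    for t in (call_rate_min, maf_min, het_diff_max, animal_call_rate_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    D = geno.dosages
    a_call = 1.0 - np.isnan(D).mean(axis=1)
    keep_a = a_call >= animal_call_rate_min
    animal_metrics = pd.DataFrame(
        {"animal": geno.ids, "call_rate": a_call, "kept": keep_a}
    )
    D = D[keep_a]
    sexes = geno.sexes[keep_a] if geno.sexes is not None else None

    with np.errstate(invalid="ignore"):
        call = 1.0 - np.isnan(D).mean(axis=0)
        p = np.nanmean(D, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        obs_het = np.nanmean(D == 1.0, axis=0)
        if sexes is not None:
            females = sexes == "F"
            if females.any():
                het_f = np.nanmean(D[females] == 1.0, axis=0)
                obs_het = np.where(geno.is_x(), het_f, obs_het)
        exp_het = 2.0 * p * (1.0 - p)
        het_diff = np.abs(obs_het - exp_het)

    reason = np.full(geno.n_snps, "", dtype=object)
    reason[het_diff >= het_diff_max] = "het_diff"
    reason[maf <= maf_min] = "maf"
    reason[call <= call_rate_min] = "call_rate"
    kept = reason == ""
    snp_metrics = pd.DataFrame(
        {
            "snp": geno.snps["snp"],
            "call_rate": call,
            "maf": maf,
            "het_diff": het_diff,
            "kept": kept,
            "reason": reason,
        }
    )
    if not kept.any():
        raise ValueError("genotype QC removed every SNP")
    out = GenotypeMatrix(
        geno.ids[keep_a], geno.snps.loc[kept], D[:, kept], sexes
    )
    report = QCReport(
        snp_metrics,
        animal_metrics,
        {
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "het_diff_max": het_diff_max,
            "animal_call_rate_min": animal_call_rate_min,
        },
    )
    return out, report


def build_G(
    geno: GenotypeMatrix,
    freq_source: str = "observed",
    freqs: np.ndarray | None = None,
    blend_a22: RelationshipMatrix | None = None,
    blend_weight: float = 0.05,
) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``G = Z Zᵀ / (2 Σ p(1−p))`` with ``Z`` the dosage matrix centred by
    twice the allele frequency.  When ``blend_a22`` is given, returns
    ``(1−w) G + w A22`` which is guaranteed positive definite for
    ``w > 0``.
    """
    if geno.n_animals < 2 or geno.n_snps < 1:
        raise ValueError("need at least 2 genotyped animals and 1 SNP")
    if freq_source == "observed":
        p = geno.allele_frequencies()
    elif freq_source == "supplied":
        if freqs is None:
            raise ValueError("freq_source='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
    else:
        raise ValueError(f"unknown freq_source {freq_source!r}")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: G denominator is zero")
    Z = geno.centered(p)
    G = (Z @ Z.T) / denom
    if blend_a22 is not None:
        if not np.array_equal(blend_a22.ids, geno.ids):
            A22 = blend_a22.subset(geno.ids).to_dense()
        else:
            A22 = blend_a22.to_dense()
        G = (1.0 - blend_weight) * G + blend_weight * A22
    return RelationshipMatrix(geno.ids, G, "G")


def build_Hinv(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix | None,
    G_inv: RelationshipMatrix | None,
    genotyped_ids=(),
) -> RelationshipMatrix:
    """Hybrid inverse: A⁻¹ plus the genotyped-block correction G⁻¹ − A22⁻¹."""
    genotyped_ids = np.asarray(list(genotyped_ids))
    H = A_inv.to_dense().copy()
    if genotyped_ids.size:
        if A22_inv is None or G_inv is None:
            raise ValueError("genotyped animals present but G⁻¹/A22⁻¹ missing")
        for m, nm in ((A22_inv, "A22_inv"), (G_inv, "G_inv")):
            if not np.array_equal(m.ids, genotyped_ids):
                raise ValueError(f"{nm} ids do not match genotyped_ids")
        pos = {a: i for i, a in enumerate(A_inv.ids)}
        try:
            idx = np.array([pos[a] for a in genotyped_ids])
        except KeyError as e:
            raise ValueError(f"genotyped animal {e.args[0]} not in A⁻¹") from None
        H[np.ix_(idx, idx)] += G_inv.to_dense() - A22_inv.to_dense()
    return RelationshipMatrix(A_inv.ids, H, "Hinv")


def invert_relationship(mat: RelationshipMatrix, kind: str | None = None) -> RelationshipMatrix:
    """Dense inverse of a relationship matrix (errors on singular G)."""
    dense = mat.to_dense()
    try:
        c = np.linalg.cholesky(dense)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"{mat.kind} is singular or indefinite; blend G toward A22 "
            "(build_G(..., blend_a22=A22)) before inverting"
        ) from None
    inv = np.linalg.inv(c)
    inv = inv.T @ inv
    return RelationshipMatrix(mat.ids, inv, kind or (mat.kind + "inv"))
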