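"""Single-step genomic reaction-norm mixed model and AI-REML estimation.

The model for a record of animal j in contemporary group i is

    y_ij = x'_j β + b θ̂_i + Σ_n (n0_j + n1_j θ̂_i) + e_ij ,

where each random effect n ∈ {a, pe, ce} contributes an intercept and a
slope on the environmental gradient θ̂.  The additive pairs have
covariance H ⊗ B_a with H the hybrid pedigree–genomic relationship
matrix; pe and ce pairs are i.i.d. with their own 2×2 blocks.  The
residual is homogeneous (RNM1, Var = σ²_e) or exponentially
heteroscedastic (RNM2, Var = exp(d0 + d1 θ̂_i)); RNM1 is run as RNM2
with d1 fixed at zero, so a single code path serves both.

Variance components are estimated by average-information REML on an
unconstrained parameterization (log variances, Fisher-z correlations,
raw d0/d1), which keeps every 2×2 block positive semi-definite by
construction.  AI steps are halved when they fail to improve the
restricted likelihood, with an EM update as fallback; standard errors
come from the inverse AI matrix at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_solve, cholesky
from scipy.linalg.lapack import dpotri

from .envgrad import EnvGradient, ModelSpec, PhenotypeTable
from .relmat import RelationshipMatrix

__all__ = [
    "VarCompSet",
    "RNMFit",
    "assemble_mme",
    "reml_fit",
    "residual_variance_at",
    "choose_model",
    "REMLError",
]

R_BOUND = 0.9999  # correlation boundary, reported when REML pins |r| there


class REMLError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class VarCompSet:
    """Intercept/slope (co)variance blocks plus residual parameters."""

    blocks: dict  # effect -> 2×2 ndarray
    residual_kind: str = "homogeneous"  # or "heteroscedastic"
    d0: float = 0.0  # σ²_e = exp(d0) under RNM1
    d1: float = 0.0
    se: dict = field(default_factory=dict)  # parameter name -> SE

    @property
    def sigma2_e(self) -> float:
        return float(np.exp(self.d0))

    def block(self, effect: str) -> np.ndarray:
        return np.asarray(self.blocks[effect], dtype=float)

    def n_parameters(self) -> int:
        k = 3 * len(self.blocks) + 1  # three per block, plus d0
        if self.residual_kind == "heteroscedastic":
            k += 1
        return k

    def parameter_names(self):
        names = []
        for eff in self.blocks:
            names += [f"{eff}_var0", f"{eff}_cov01", f"{eff}_var1"]
        names.append("d0")
        if self.residual_kind == "heteroscedastic":
            names.append("d1")
        return names

    def validate(self) -> None:
        for eff, B in self.blocks.items():
            B = np.asarray(B, float)
            if B.shape != (2, 2) or abs(B[0, 1] - B[1, 0]) > 1e-10:
                raise ValueError(f"block {eff!r} must be symmetric 2×2")
            if np.linalg.eigvalsh(B)[0] < -1e-10:
                raise ValueError(f"block {eff!r} not positive semi-definite")


def residual_variance_at(varcomp: VarCompSet, theta) -> np.ndarray | float:
    """exp(d0 + d1 θ); collapses to σ²_e for a homogeneous fit."""
    theta = np.asarray(theta, dtype=float)
    if varcomp.residual_kind == "heteroscedastic":
        out = np.exp(varcomp.d0 + varcomp.d1 * theta)
    else:
        out = np.full(theta.shape, varcomp.sigma2_e)
    return out if out.ndim else float(out)


@dataclass
class RNMFit:
    """REML solution: fixed effects, per-animal coefficients, fit indices."""

    beta: pd.Series  # fixed-effect solutions by design-column name
    b: float  # overall fixed regression on θ̂
    solutions: dict  # effect -> DataFrame(id, intercept, slope, se_int, se_slo)
    loglik: float
    aic: float
    converged: bool
    n_iterations: int
    trace: list  # per-iteration restricted logL
    model: str  # RNM1 / RNM2
    n_records: int
    data_key: float  # checksum of y, used to guard model comparisons

    def solutions_for(self, effect: str) -> pd.DataFrame:
        return self.solutions[effect]


# ---------------------------------------------------------------------------
# design / MME assembly


class MMESystem:
    """Henderson's mixed-model equations for one reaction-norm model.

    Holds the sparse design ``T = [X | W]``, the per-record gradient
    values θ, the random-effect layout, and K⁻¹ for the additive effect
    (H⁻¹).  Coefficient matrices for given variance components are built
    on demand.
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        gradient: EnvGradient,
        spec: ModelSpec,
        hinv: RelationshipMatrix,
        cg_as_class: bool = False,
        include_theta: bool = True,
    ):
        df = pheno.df
        self.y = df["y"].to_numpy(float)
        self.n = len(df)
        self.records = df.reset_index(drop=True)
        self.theta = gradient.theta_for(df["cg"].astype(str).to_numpy())

        # fixed part: systematic effects + overall regression on θ̂
        from .envgrad import _design_columns

        X, names = _design_columns(df, spec, cg=cg_as_class, cg_sum_to_zero=False)
        if include_theta:
            X = np.column_stack([X, self.theta])
            names = names + ["theta"]
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.X = X
        self.fixed_names = names
        self.p = X.shape[1]

        # random-effect layout: [a0 a1 | pe0 pe1 | ce0 ce1]
        self.effects = list(spec.random_effects)
        self.levels: dict[str, np.ndarray] = {}
        self.slices: dict[str, slice] = {}
        blocks_design = []
        offset = self.p
        rows = np.arange(self.n)
        for eff in self.effects:
            if eff == "a":
                ids = hinv.ids
            elif eff == "pe":
                ids = np.unique(df["animal"].to_numpy())
            elif eff == "ce":
                if "litter" not in df.columns:
                    raise ValueError("litter column required for the ce effect")
                ids = np.unique(df["litter"].to_numpy())
            pos = {v: k for k, v in enumerate(ids)}
            key = {"a": "animal", "pe": "animal", "ce": "litter"}[eff]
            try:
                col = np.array([pos[v] for v in df[key]])
            except KeyError as e:
                raise ValueError(
                    f"record {key} {e.args[0]} missing from the {eff} index"
                ) from None
            q = len(ids)
            Z0 = sparse.csr_matrix(
                (np.ones(self.n), (rows, col)), shape=(self.n, q)
            )
            Z1 = sparse.csr_matrix((self.theta, (rows, col)), shape=(self.n, q))
            blocks_design.append(sparse.hstack([Z0, Z1]))
            self.levels[eff] = np.asarray(ids)
            self.slices[eff] = slice(offset, offset + 2 * q)
            offset += 2 * q
        self.m = offset
        self.T = sparse.hstack(
            [sparse.csr_matrix(self.X)] + blocks_design, format="csr"
        )
        self.hinv = hinv.to_dense()
        if not np.array_equal(hinv.ids, self.levels.get("a", hinv.ids)):
            raise ValueError("H⁻¹ ids out of order")
        sign, self.logdet_hinv = np.linalg.slogdet(self.hinv)
        if sign <= 0:
            raise ValueError("H⁻¹ is not positive definite")

    # -- per-iteration pieces -------------------------------------------
    def residual_variances(self, vc: VarCompSet) -> np.ndarray:
        return np.exp(vc.d0 + vc.d1 * self.theta)

    def kinv(self, eff: str) -> np.ndarray | None:
        return self.hinv if eff == "a" else None  # None means identity

    def coefficient_matrix(self, vc: VarCompSet):
        """Dense C, right-hand side, and log|G| for the MME."""
        r = self.residual_variances(vc)
        Rinv = sparse.diags(1.0 / r)
        C = (self.T.T @ Rinv @ self.T).toarray()
        logdet_g = 0.0
        for eff in self.effects:
            B = vc.block(eff)
            Binv = np.linalg.inv(B)
            sl = self.slices[eff]
            q = (sl.stop - sl.start) // 2
            ki = self.kinv(eff)
            if ki is None:
                idx = np.arange(sl.start, sl.stop)
                qi = np.arange(q)
                for s in range(2):
                    for t in range(2):
                        C[idx[s * q + qi], idx[t * q + qi]] += Binv[s, t]
                logdet_k = 0.0
            else:
                C[sl, sl] += np.kron(Binv, ki)
                logdet_k = -self.logdet_hinv
            sign, logdet_b = np.linalg.slogdet(B)
            if sign <= 0:
                raise REMLError(f"block {eff!r} became singular")
            logdet_g += q * logdet_b + 2.0 * logdet_k
        rhs = self.T.T @ (self.y / r)
        return C, rhs, logdet_g

    def loglik(self, vc: VarCompSet, factor=None):
        """Restricted logL = −½(log|R| + log|G| + log|C| + y'Py)."""
        r = self.residual_variances(vc)
        if factor is None:
            C, rhs, logdet_g = self.coefficient_matrix(vc)
            L = cholesky(C, lower=True)
        else:
            L, rhs, logdet_g = factor
        sol = cho_solve((L, True), rhs)
        logdet_c = 2.0 * np.sum(np.log(np.diag(L)))
        ypy = float(self.y @ (self.y / r) - sol @ rhs)
        ll = -0.5 * (np.sum(np.log(r)) + logdet_g + logdet_c + ypy)
        return ll, sol


def assemble_mme(
    pheno: PhenotypeTable,
    gradient: EnvGradient,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    varcomp: VarCompSet,
    cg_as_class: bool = False,
    include_theta: bool = True,
):
    """Build the MME for fixed variance components.

    Returns ``(system, C, rhs)`` where ``C x = rhs`` yields the BLUE of
    the fixed effects and BLUP of all intercept/slope coefficients.
    """
    varcomp.validate()
    sys_ = MMESystem(
        pheno, gradient, spec, hinv, cg_as_class=cg_as_class,
        include_theta=include_theta,
    )
    C, rhs, _ = sys_.coefficient_matrix(varcomp)
    return sys_, C, rhs


# ---------------------------------------------------------------------------
# unconstrained parameterization


def _block_to_t(B: np.ndarray) -> np.ndarray:
    v0, v1 = B[0, 0], B[1, 1]
    r = B[0, 1] / np.sqrt(v0 * v1)
    r = np.clip(r, -R_BOUND, R_BOUND)
    return np.array([np.log(v0), np.log(v1), np.arctanh(r)])


def _t_to_block(t: np.ndarray) -> np.ndarray:
    v0, v1 = np.exp(t[0]), np.exp(t[1])
    r = np.tanh(t[2])
    c = r * np.sqrt(v0 * v1)
    return np.array([[v0, c], [c, v1]])


def _block_jacobian(t: np.ndarray) -> np.ndarray:
    """d(v0, c01, v1)/d(t0, t1, t2), rows ordered (v0, c01, v1)."""
    v0, v1 = np.exp(t[0]), np.exp(t[1])
    r = np.tanh(t[2])
    s = np.sqrt(v0 * v1)
    J = np.zeros((3, 3))
    J[0, 0] = v0
    J[2, 1] = v1
    J[1, 0] = 0.5 * r * s
    J[1, 1] = 0.5 * r * s
    J[1, 2] = (1.0 - r**2) * s
    return J


# ---------------------------------------------------------------------------
# AI-REML


def _default_start(sys_: MMESystem, model: str) -> VarCompSet:
    vary = float(np.var(sys_.y, ddof=1))
    blocks = {}
    for i, eff in enumerate(sys_.effects):
        v0 = 0.5 * vary if eff == "a" else 0.1 * vary
        blocks[eff] = np.array([[v0, 0.0], [0.0, 0.1 * vary]])
    kind = "heteroscedastic" if model == "RNM2" else "homogeneous"
    frac = max(1.0 - 0.5 - 0.2 * (len(sys_.effects) - 1), 0.2)
    return VarCompSet(blocks, kind, d0=float(np.log(frac * vary)), d1=0.0)


def _pack(vc: VarCompSet, sys_: MMESystem) -> np.ndarray:
    parts = [_block_to_t(vc.block(eff)) for eff in sys_.effects]
    parts.append([vc.d0])
    if vc.residual_kind == "heteroscedastic":
        parts.append([vc.d1])
    return np.concatenate(parts)


def _unpack(t: np.ndarray, vc: VarCompSet, sys_: MMESystem) -> VarCompSet:
    blocks = {}
    for i, eff in enumerate(sys_.effects):
        blocks[eff] = _t_to_block(t[3 * i : 3 * i + 3])
    k = 3 * len(sys_.effects)
    d0 = float(t[k])
    d1 = float(t[k + 1]) if vc.residual_kind == "heteroscedastic" else 0.0
    return VarCompSet(blocks, vc.residual_kind, d0=d0, d1=d1)


def _gradient_and_ai(sys_: MMESystem, vc: VarCompSet, C, rhs, L, Cinv, sol):
    """Score vector and average-information matrix on the original scale.

    Original-scale parameters per block are (σ²_0, σ_01, σ²_1), then d0
    (and d1 under RNM2).  Uses the standard MME identities; every AI
    entry is formed from 'working vectors' V_k P y and solves against
    the already-factorized coefficient matrix.
    """
    theta = sys_.theta
    r = sys_.residual_variances(vc)
    e = sys_.y - sys_.T @ sol
    py = e / r

    Ebasis = [
        np.array([[1.0, 0.0], [0.0, 0.0]]),
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.array([[0.0, 0.0], [0.0, 1.0]]),
    ]
    grads = []
    workvecs = []
    for eff in sys_.effects:
        B = vc.block(eff)
        Binv = np.linalg.inv(B)
        sl = sys_.slices[eff]
        q = (sl.stop - sl.start) // 2
        u = sol[sl]
        U = u.reshape(2, q).T  # columns: intercept, slope solutions
        ki = sys_.kinv(eff)
        Cuu = Cinv[sl, sl]
        for E in Ebasis:
            M = Binv @ E @ Binv
            # tr(G⁻¹ dG) = q·tr(B⁻¹E)
            t1 = q * np.trace(Binv @ E)
            # tr(C⁻¹uu (M ⊗ K⁻¹))
            t2 = 0.0
            for s in range(2):
                for tt in range(2):
                    if M[s, tt] == 0.0:
                        continue
                    blockst = Cuu[s * q : (s + 1) * q, tt * q : (tt + 1) * q]
                    if ki is None:
                        t2 += M[s, tt] * np.trace(blockst)
                    else:
                        t2 += M[s, tt] * np.sum(blockst * ki.T)
            # quadratic term u' (M ⊗ K⁻¹) u
            KU = U if ki is None else ki @ U
            t3 = float(np.sum((U @ M.T) * KU))
            grads.append(-0.5 * (t1 - t2 - t3))
            # working vector W (E B⁻¹ ⊗ I) u
            V = U @ (E @ Binv).T
            w = np.zeros(sys_.m)
            w[sl] = V.T.ravel()
            workvecs.append(sys_.T @ w)
    # residual parameters
    res_g = [np.ones(sys_.n)]
    if vc.residual_kind == "heteroscedastic":
        res_g.append(theta)
    Tcsr = sys_.T
    for g in res_g:
        # tr(P dR) = Σ g − tr(C⁻¹ T' diag(g/r) T)
        D = sparse.diags(g / r)
        M2 = (Tcsr.T @ D @ Tcsr).toarray()
        t1 = float(np.sum(g))
        t2 = float(np.sum(Cinv * M2.T))
        t3 = float(np.sum(g * py * e))
        grads.append(-0.5 * (t1 - t2 - t3))
        workvecs.append(g * e)

    k = len(workvecs)
    AI = np.zeros((k, k))
    # P w = R⁻¹(w − T C⁻¹ T' R⁻¹ w)
    pw = []
    for w in workvecs:
        rw = w / r
        solw = cho_solve((L, True), Tcsr.T @ rw)
        pw.append((w - Tcsr @ solw) / r)
    for i in range(k):
        for j in range(i, k):
            AI[i, j] = AI[j, i] = 0.5 * float(workvecs[i] @ pw[j])
    return np.array(grads), AI


def _jacobian(vc: VarCompSet, sys_: MMESystem, t: np.ndarray) -> np.ndarray:
    """d(original params)/d(unconstrained params), block diagonal."""
    nb = len(sys_.effects)
    nres = 2 if vc.residual_kind == "heteroscedastic" else 1
    k = 3 * nb + nres
    J = np.zeros((k, k))
    for i in range(nb):
        J[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = _block_jacobian(
            t[3 * i : 3 * i + 3]
        )
    for i in range(nres):
        J[3 * nb + i, 3 * nb + i] = 1.0
    return J


def _em_update(sys_: MMESystem, vc: VarCompSet, Cinv, sol) -> VarCompSet:
    """EM-REML update for the covariance blocks (residual kept fixed)."""
    blocks = {}
    for eff in sys_.effects:
        sl = sys_.slices[eff]
        q = (sl.stop - sl.start) // 2
        u = sol[sl]
        U = u.reshape(2, q).T
        ki = sys_.kinv(eff)
        KU = U if ki is None else ki @ U
        quad = U.T @ KU
        tr = np.zeros((2, 2))
        Cuu = Cinv[sl, sl]
        for s in range(2):
            for t in range(2):
                blockst = Cuu[s * q : (s + 1) * q, t * q : (t + 1) * q]
                tr[s, t] = (
                    np.trace(blockst) if ki is None else np.sum(blockst * ki.T)
                )
        B = (quad + 0.5 * (tr + tr.T)) / q
        blocks[eff] = 0.5 * (B + B.T)
    return VarCompSet(blocks, vc.residual_kind, vc.d0, vc.d1)


def reml_fit(
    pheno: PhenotypeTable,
    gradient: EnvGradient,
    spec: ModelSpec,
    hinv: RelationshipMatrix,
    model: str = "RNM2",
    init: VarCompSet | None = None,
    tol: float = 1e-8,
    logl_tol: float = 1e-9,
    grad_tol: float = 0.01,
    max_rounds: int = 100,
    cg_as_class: bool = False,
    verbose: bool = False,
) -> tuple[VarCompSet, RNMFit]:
    """Estimate variance components by AI-REML and solve the MME.

    Convergence is declared when the largest relative change of any
    original-scale parameter falls below ``tol``, the restricted logL
    changes by less than ``logl_tol``, or the projected gradient (active
    bounds excluded) drops below ``grad_tol`` — the latter handles fits
    whose optimum sits on the correlation boundary, where EM-style
    progress slows to a crawl.  Raises :class:`REMLError` (with the
    likelihood trace attached) if none of this happens in
    ``max_rounds``.
    """
    if model not in ("RNM1", "RNM2"):
        raise ValueError("model must be 'RNM1' or 'RNM2'")
    sys_ = MMESystem(pheno, gradient, spec, hinv, cg_as_class=cg_as_class)
    vc = init if init is not None else _default_start(sys_, model)
    if init is not None:
        kind = "heteroscedastic" if model == "RNM2" else "homogeneous"
        vc = VarCompSet(
            {e: vc.block(e).copy() for e in vc.blocks}, kind, vc.d0, vc.d1
        )
    vary = float(np.var(sys_.y, ddof=1))
    lo, hi = np.log(1e-8 * vary), np.log(1e6 * vary)

    t = _pack(vc, sys_)
    lower, upper = _bounds(sys_, vc, lo, hi)
    trace = []
    converged = False
    ridge = 1e-6
    for it in range(max_rounds):
        vc = _unpack(t, vc, sys_)
        C, rhs, logdet_g = sys_.coefficient_matrix(vc)
        try:
            L = cholesky(C, lower=True)
        except np.linalg.LinAlgError:
            raise REMLError("MME coefficient matrix not positive definite",
                            trace) from None
        ll, sol = sys_.loglik(vc, factor=(L, rhs, logdet_g))
        trace.append(ll)
        if verbose:
            print(f"iter {it:3d} logL {ll:.6f}")
        inv, info = dpotri(L, lower=1)
        if info != 0:
            raise REMLError("inversion of the coefficient matrix failed", trace)
        Cinv = inv + np.tril(inv, -1).T
        grad, AI = _gradient_and_ai(sys_, vc, C, rhs, L, Cinv, sol)
        J = _jacobian(vc, sys_, t)
        grad_t = J.T @ grad
        AI_t = J.T @ AI @ J
        # projected gradient: ignore components pushing against a bound
        at_lo = t <= lower + 1e-9
        at_hi = t >= upper - 1e-9
        proj = grad_t.copy()
        proj[at_lo & (proj < 0)] = 0.0
        proj[at_hi & (proj > 0)] = 0.0
        if np.abs(proj).max() < grad_tol:
            converged = True
            break
        # Levenberg-damped AI step; raise the ridge until logL improves
        scale = max(np.trace(AI_t) / len(t), 1.0)
        improved = False
        new_t, new_ll = t, ll
        for _ in range(15):
            try:
                step = np.linalg.solve(
                    AI_t + ridge * scale * np.eye(len(t)), proj
                )
            except np.linalg.LinAlgError:
                step = proj / scale
            step[at_lo & (step < 0)] = 0.0
            step[at_hi & (step > 0)] = 0.0
            smax = np.abs(step).max()
            if smax > 3.0:  # keep log-scale moves sane far from the optimum
                step = step * (3.0 / smax)
            cand = _clip_t(t + step, sys_, vc, lo, hi)
            try:
                ll_c, _ = sys_.loglik(_unpack(cand, vc, sys_))
            except (np.linalg.LinAlgError, REMLError):
                ridge *= 10.0
                continue
            if ll_c >= ll - 1e-12:
                new_t, new_ll, improved = cand, ll_c, True
                ridge = max(ridge / 10.0, 1e-8)
                break
            ridge *= 10.0
        if not improved:
            # EM fallback for the blocks; residual parameters held
            vc_em = _em_update(sys_, vc, Cinv, sol)
            cand = _clip_t(_pack(vc_em, sys_), sys_, vc, lo, hi)
            try:
                ll_c, _ = sys_.loglik(_unpack(cand, vc, sys_))
                if ll_c >= ll - 1e-12:
                    new_t, new_ll, improved = cand, ll_c, True
            except (np.linalg.LinAlgError, REMLError):
                pass
        old_params = _original_params(t, vc, sys_)
        new_params = _original_params(new_t, vc, sys_)
        denom = np.maximum(np.abs(old_params), 1e-8 * vary)
        rel = np.max(np.abs(new_params - old_params) / denom)
        dll = abs(new_ll - ll)
        t = new_t
        if rel < tol or dll < logl_tol or not improved:
            converged = True
            break
    else:
        raise REMLError(
            f"REML did not converge in {max_rounds} rounds", trace
        )

    # final quantities at the converged parameters
    vc = _unpack(t, vc, sys_)
    C, rhs, logdet_g = sys_.coefficient_matrix(vc)
    L = cholesky(C, lower=True)
    ll, sol = sys_.loglik(vc, factor=(L, rhs, logdet_g))
    inv, _ = dpotri(L, lower=1)
    Cinv = inv + np.tril(inv, -1).T
    grad, AI = _gradient_and_ai(sys_, vc, C, rhs, L, Cinv, sol)
    se = _parameter_se(AI, vc)
    vc.se.update(se)

    sol_se = np.sqrt(np.clip(np.diag(Cinv), 0.0, None))
    solutions = {}
    for eff in sys_.effects:
        sl = sys_.slices[eff]
        q = (sl.stop - sl.start) // 2
        solutions[eff] = pd.DataFrame(
            {
                "id": sys_.levels[eff],
                "intercept": sol[sl][:q],
                "slope": sol[sl][q:],
                "se_int": sol_se[sl.start : sl.start + q],
                "se_slo": sol_se[sl.start + q : sl.stop],
            }
        )
    beta = pd.Series(sol[: sys_.p], index=sys_.fixed_names)
    n_par = vc.n_parameters()
    fit = RNMFit(
        beta=beta,
        b=float(beta["theta"]),
        solutions=solutions,
        loglik=float(ll),
        aic=float(-2.0 * ll + 2.0 * n_par),
        converged=converged,
        n_iterations=len(trace),
        trace=trace,
        model=model,
        n_records=sys_.n,
        data_key=float(np.sum(sys_.y) + 1e-3 * np.sum(sys_.y**2)),
    )
    return vc, fit


def _bounds(sys_, vc, lo, hi):
    """Lower/upper bounds on the unconstrained parameter vector."""
    nb = len(sys_.effects)
    zmax = np.arctanh(R_BOUND)
    n = 3 * nb + (2 if vc.residual_kind == "heteroscedastic" else 1)
    lower = np.empty(n)
    upper = np.empty(n)
    for i in range(nb):
        lower[3 * i : 3 * i + 2] = lo
        upper[3 * i : 3 * i + 2] = hi
        lower[3 * i + 2] = -zmax
        upper[3 * i + 2] = zmax
    lower[3 * nb], upper[3 * nb] = lo, hi
    if vc.residual_kind == "heteroscedastic":
        lower[3 * nb + 1], upper[3 * nb + 1] = -5.0, 5.0
    return lower, upper


def _clip_t(t, sys_, vc, lo, hi):
    t = t.copy()
    nb = len(sys_.effects)
    zmax = np.arctanh(R_BOUND)
    for i in range(nb):
        t[3 * i] = np.clip(t[3 * i], lo, hi)
        t[3 * i + 1] = np.clip(t[3 * i + 1], lo, hi)
        t[3 * i + 2] = np.clip(t[3 * i + 2], -zmax, zmax)
    t[3 * nb] = np.clip(t[3 * nb], lo, hi)
    if vc.residual_kind == "heteroscedastic" and len(t) > 3 * nb + 1:
        t[3 * nb + 1] = np.clip(t[3 * nb + 1], -5.0, 5.0)
    return t


def _original_params(t, vc, sys_):
    out = []
    for i, eff in enumerate(sys_.effects):
        B = _t_to_block(t[3 * i : 3 * i + 3])
        out += [B[0, 0], B[0, 1], B[1, 1]]
    k = 3 * len(sys_.effects)
    out.append(np.exp(t[k]))
    if vc.residual_kind == "heteroscedastic":
        out.append(t[k + 1])
    return np.array(out)


def _parameter_se(AI: np.ndarray, vc: VarCompSet) -> dict:
    names = vc.parameter_names()
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    return dict(zip(names, se))


def choose_model(fit1: RNMFit, fit2: RNMFit) -> str:
    """AIC choice between the homogeneous and heteroscedastic fits.

    Ties favour RNM1 (parsimony).  Refuses to compare fits obtained on
    different data.
    """
    if fit1.n_records != fit2.n_records or not np.isclose(
        fit1.data_key, fit2.data_key
    ):
        raise ValueError("fits were obtained on different data")
    models = {fit1.model: fit1, fit2.model: fit2}
    if set(models) != {"RNM1", "RNM2"}:
        raise ValueError("need one RNM1 fit and one RNM2 fit")
    return "RNM2" if models["RNM2"].aic < models["RNM1"].aic else "RNM1"
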