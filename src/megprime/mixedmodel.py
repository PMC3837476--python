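"""Gaussian linear mixed models with crossed random intercepts.

The model underlying every test in this package is

    y = X @ beta + Z_s u_s + Z_i u_i + eps,
    u_s ~ N(0, sigma_s^2 I),  u_i ~ N(0, sigma_i^2 I),  eps ~ N(0, sigma^2 I),

with one random intercept per subject and one per item (crossed, not
nested).  Fitting profiles the likelihood over the two variance *ratios*
lambda_s = sigma_s^2 / sigma^2 and lambda_i = sigma_i^2 / sigma^2: for a
given pair of ratios the fixed effects, the residual variance and the
(restricted) log-likelihood have closed forms, so only a 2-D numerical
optimization remains.  All n-dimensional products are reduced to
q = (n_subjects + n_items)-dimensional ones through the Woodbury identity,
which is what makes millisecond-by-millisecond refits and batched
permutation statistics affordable.

Conventions
-----------
* t-values are coefficient / SE without a degrees-of-freedom correction,
  to go with the fixed |t| > 1.96 cluster-forming threshold used downstream.
* REML is used when a single fit's t-values are reported; likelihood-ratio
  tests of nested fixed-effect structures always refit both models with ML.
* Variance components are bounded at zero (ratios parameterized as eta^2).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_TINY = 1e-300

# reference levels for treatment coding of two-level factors; the first
# sorted level is the reference, so e.g. the prime_type coefficient is the
# unrelated - related difference (positive = RT facilitation by the prime)
__all__ = [
    "GroupStructure",
    "ModelFit",
    "CrossedLMM",
    "fit_lmm",
    "lrt_nested",
    "mc_pvalue_fixed_effect",
    "build_design",
]


# --------------------------------------------------------------------------
# design-matrix helpers
# --------------------------------------------------------------------------

def _term_column(trials: pd.DataFrame, term: str) -> tuple[np.ndarray, str]:
    v = trials[term]
    if pd.api.types.is_numeric_dtype(v):
        return v.to_numpy(dtype=float), term
    levels = sorted(pd.unique(v.astype(str)))
    if len(levels) == 1:
        raise ValueError(f"term {term!r} is constant")
    if len(levels) != 2:
        raise ValueError(f"only two-level factors are supported, {term!r} has {levels}")
    coded = (v.astype(str) == levels[1]).to_numpy(dtype=float)
    return coded, f"{term}[{levels[1]}]"


def build_design(
    trials: pd.DataFrame,
    terms: Sequence[str] = ("prime_type",),
    interactions: Sequence[tuple[str, str]] = (),
    intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Named design matrix from trial-table columns.

    Numeric columns enter as-is; two-level factors are treatment coded
    against their first sorted level.  Interactions are products of the
    coded columns, named ``"a:b"``.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(trials)))
        names.append("Intercept")
    coded: dict[str, np.ndarray] = {}
    for term in terms:
        c, name = _term_column(trials, term)
        coded[term] = c
        cols.append(c)
        names.append(name)
    for a, b in interactions:
        ca = coded[a] if a in coded else _term_column(trials, a)[0]
        cb = coded[b] if b in coded else _term_column(trials, b)[0]
        cols.append(ca * cb)
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # greedy scan for the columns that break independence
        bad = []
        kept: list[int] = []
        for j in range(p):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")


# --------------------------------------------------------------------------
# grouping structure + Woodbury algebra
# --------------------------------------------------------------------------

class GroupStructure:
    """Subject/item grouping with precomputed crossproducts.

    Holds the sparse random-effects design Z = [Z_subject | Z_item] and
    Z'Z, so that for any columns a, b with known Z'a, Z'b and a'b the
    whitened product a' W^{-1} b (W = I + Z diag(lam) Z') costs only
    q-dimensional algebra.
    """

    def __init__(self, subjects, items):
        subjects = np.asarray(subjects)
        items = np.asarray(items)
        if subjects.shape != items.shape or subjects.ndim != 1:
            raise ValueError("subjects and items must be equal-length 1-D")
        self.subject_levels, self.si = np.unique(subjects, return_inverse=True)
        self.item_levels, self.ii = np.unique(items, return_inverse=True)
        self.n = len(subjects)
        self.n_subjects = len(self.subject_levels)
        self.n_items = len(self.item_levels)
        if self.n_subjects < 2 or self.n_items < 2:
            raise ValueError("need at least 2 subjects and 2 items")
        self.q = self.n_subjects + self.n_items
        rows = np.arange(self.n)
        ones = np.ones(self.n)
        Zs = sparse.csr_matrix((ones, (rows, self.si)), shape=(self.n, self.n_subjects))
        Zi = sparse.csr_matrix((ones, (rows, self.ii)), shape=(self.n, self.n_items))
        self.Z = sparse.hstack([Zs, Zi]).tocsr()
        self.ZtZ = np.asarray((self.Z.T @ self.Z).todense())

    def Zt(self, M: np.ndarray) -> np.ndarray:
        """Z' @ M as a dense array (M is (n,) or (n, m))."""
        out = self.Z.T @ M
        return np.asarray(out)

    def lam_vector(self, lam_s: float, lam_i: float) -> np.ndarray:
        return np.concatenate(
            [np.full(self.n_subjects, lam_s), np.full(self.n_items, lam_i)]
        )


def _whiten_factor(struct: GroupStructure, lam_s: float, lam_i: float):
    """Cholesky factor of C = I_q + D^1/2 Z'Z D^1/2 plus log|W|.

    Returns (sd, L, logdetW) with sd = sqrt(diag D).  W^{-1}-products follow
    as a'W^{-1}b = a'b - (sd*Z'a)' C^{-1} (sd*Z'b).
    """
    sd = np.sqrt(struct.lam_vector(lam_s, lam_i))
    C = np.eye(struct.q) + (sd[:, None] * struct.ZtZ) * sd[None, :]
    L = np.linalg.cholesky(C)
    logdetW = 2.0 * np.sum(np.log(np.diag(L)))
    return sd, L, logdetW


def _whitened_crossprod(sd, L, ZtM: np.ndarray, MtM: np.ndarray) -> np.ndarray:
    T = solve_triangular(L, sd[:, None] * ZtM, lower=True)
    return MtM - T.T @ T


def _profile(MtWM: np.ndarray, logdetW: float, n: int, p: int, method: str):
    """Closed-form profile given whitened crossproducts of M = [X, y].

    Returns (criterion, beta, rss, sigma2, XtWX); criterion = -2 log(L).
    """
    XtWX = MtWM[:p, :p]
    XtWy = MtWM[:p, p]
    ytWy = MtWM[p, p]
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
    rss = max(float(ytWy - XtWy @ beta), 0.0)
    if method == "ML":
        dof = n
        sigma2 = rss / dof
        crit = logdetW + n * np.log(max(sigma2, _TINY)) + n * (1.0 + _LOG2PI)
    else:  # REML
        dof = n - p
        sigma2 = rss / dof
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        crit = (
            logdetW
            + logdetXtWX
            + dof * np.log(max(sigma2, _TINY))
            + dof * (1.0 + _LOG2PI)
        )
    return crit, beta, rss, sigma2, XtWX


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ModelFit:
    """Fitted crossed random-intercepts model.

    ``variance_components`` is (subject, item, residual); t = coef / SE.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    variance_components: tuple[float, float, float]
    log_likelihood: float
    method: str
    converged: bool
    n_obs: int

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["variance_components"] = list(self.variance_components)
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class CrossedLMM(BaseEstimator):
    """Scikit-learn style estimator for the crossed random-intercepts LMM.

    Parameters
    ----------
    method : {"REML", "ML"}
    start : initial variance ratios (subject, item) for the optimizer.
    fixed_ratios : optional (lam_s, lam_i); skip optimization and fit the
        GLS at these ratios (useful for oracles and score-type permutation
        statistics).
    """

    def __init__(
        self,
        method: str = "REML",
        start: tuple[float, float] = (0.3, 0.3),
        fixed_ratios: tuple[float, float] | None = None,
        maxiter: int = 400,
        xatol: float = 1e-8,
        fatol: float = 1e-10,
    ):
        self.method = method
        self.start = start
        self.fixed_ratios = fixed_ratios
        self.maxiter = maxiter
        self.xatol = xatol
        self.fatol = fatol

    # -- internals --------------------------------------------------------
    @staticmethod
    def _coerce_design(X, term_names):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = (
                list(term_names)
                if term_names is not None
                else [f"x{j}" for j in range(X.shape[1])]
            )
        if len(names) != X.shape[1]:
            raise ValueError("term_names length does not match design columns")
        return X, names

    def fit(self, X, y, subjects=None, items=None, term_names=None):
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        if subjects is None or items is None:
            raise ValueError("subjects and items grouping vectors are required")
        X, names = self._coerce_design(X, term_names)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if len(y) != n:
            raise ValueError("y length does not match design")
        _check_full_rank(X, names)
        struct = GroupStructure(subjects, items)
        self.term_names_ = names
        self.struct_ = struct

        if np.ptp(y) == 0.0:
            # constant response: exact fit, zero variance everywhere
            beta = np.zeros(p)
            if "Intercept" in names:
                beta[names.index("Intercept")] = y[0] if n else 0.0
            else:
                beta = np.linalg.lstsq(X, y, rcond=None)[0]
            self._finalize(beta, np.zeros(p), (0.0, 0.0, 0.0),
                           log_likelihood=0.5 * n * (-np.log(_TINY) - _LOG2PI),
                           converged=True, ratios=(0.0, 0.0), n=n)
            return self

        M = np.column_stack([X, y])
        ZtM = struct.Zt(M)
        MtM = M.T @ M

        def crit(eta):
            lam_s, lam_i = float(eta[0]) ** 2, float(eta[1]) ** 2
            sd, L, logdetW = _whiten_factor(struct, lam_s, lam_i)
            MtWM = _whitened_crossprod(sd, L, ZtM, MtM)
            return _profile(MtWM, logdetW, n, p, self.method)[0]

        if self.fixed_ratios is not None:
            lam = (float(self.fixed_ratios[0]), float(self.fixed_ratios[1]))
            converged = True
        else:
            eta0 = np.sqrt(np.asarray(self.start, dtype=float))
            res = optimize.minimize(
                crit,
                eta0,
                method="Nelder-Mead",
                options=dict(
                    maxiter=self.maxiter, xatol=self.xatol, fatol=self.fatol
                ),
            )
            lam = (float(res.x[0]) ** 2, float(res.x[1]) ** 2)
            converged = bool(res.success) and np.isfinite(res.fun)
            if not converged:
                logger.warning("CrossedLMM optimizer did not converge: %s", res.message)

        sd, L, logdetW = _whiten_factor(struct, *lam)
        MtWM = _whitened_crossprod(sd, L, ZtM, MtM)
        criterion, beta, rss, sigma2, XtWX = _profile(MtWM, logdetW, n, p, self.method)
        cov = sigma2 * np.linalg.inv(XtWX)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        vc = (lam[0] * sigma2, lam[1] * sigma2, sigma2)
        self._finalize(beta, bse, vc, log_likelihood=-0.5 * criterion,
                       converged=converged, ratios=lam, n=n)
        return self

    def _finalize(self, beta, bse, vc, log_likelihood, converged, ratios, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), 0.0)
        self.coef_ = np.asarray(beta, dtype=float)
        self.bse_ = np.asarray(bse, dtype=float)
        self.tvalues_ = np.asarray(t, dtype=float)
        self.vc_subject_, self.vc_item_, self.vc_residual_ = vc
        self.loglik_ = float(log_likelihood)
        self.converged_ = bool(converged)
        self.ratios_ = tuple(float(r) for r in ratios)
        self.n_obs_ = int(n)

    def predict(self, X):
        X, _ = self._coerce_design(X, self.term_names_)
        return X @ self.coef_

    def result(self) -> ModelFit:
        names = self.term_names_
        return ModelFit(
            coefficients=dict(zip(names, map(float, self.coef_))),
            standard_errors=dict(zip(names, map(float, self.bse_))),
            t_values=dict(zip(names, map(float, self.tvalues_))),
            variance_components=(
                float(self.vc_subject_),
                float(self.vc_item_),
                float(self.vc_residual_),
            ),
            log_likelihood=self.loglik_,
            method=self.method,
            converged=self.converged_,
            n_obs=self.n_obs_,
        )


def fit_lmm(
    response,
    fixed_terms,
    subject_ids,
    item_ids,
    method: str = "REML",
    term_names: Sequence[str] | None = None,
    fixed_ratios: tuple[float, float] | None = None,
) -> ModelFit:
    """Fit the crossed random-intercepts LMM; thin wrapper over CrossedLMM."""
    est = CrossedLMM(method=method, fixed_ratios=fixed_ratios)
    est.fit(fixed_terms, response, subjects=subject_ids, items=item_ids,
            term_names=term_names)
    return est.result()


def _fit_ml_multi_start(X, y, subjects, items, term_names, starts):
    """ML fit taking the best of several optimizer starts (for LRT stability)."""
    best = None
    for s in starts:
        est = CrossedLMM(method="ML", start=s)
        est.fit(X, y, subjects=subjects, items=items, term_names=term_names)
        if best is None or est.loglik_ > best.loglik_:
            best = est
    return best


def lrt_nested(
    response,
    fixed_terms_reduced,
    fixed_terms_full,
    subject_ids,
    item_ids,
    names_reduced: Sequence[str] | None = None,
    names_full: Sequence[str] | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures (both ML).

    Returns (chi_sq, df, p) with chi_sq = max(0, 2 * (ll_full - ll_reduced)).
    """
    Xr, nr = CrossedLMM._coerce_design(fixed_terms_reduced, names_reduced)
    Xf, nf = CrossedLMM._coerce_design(fixed_terms_full, names_full)
    if not set(nr) <= set(nf) or Xf.shape[1] <= Xr.shape[1]:
        raise ValueError("reduced terms must be a strict subset of full terms")
    df = Xf.shape[1] - Xr.shape[1]
    if np.linalg.matrix_rank(Xf) == np.linalg.matrix_rank(Xr):
        # the added columns lie in the reduced span (e.g. an identically
        # zero interaction): the models are identical, chi^2 is exactly 0
        return 0.0, int(df), 1.0
    red = _fit_ml_multi_start(Xr, response, subject_ids, item_ids, nr, [(0.3, 0.3)])
    warm = (max(red.ratios_[0], 1e-4), max(red.ratios_[1], 1e-4))
    full = _fit_ml_multi_start(
        Xf, response, subject_ids, item_ids, nf, [(0.3, 0.3), warm]
    )
    chi_sq = max(0.0, 2.0 * (full.loglik_ - red.loglik_))
    p = float(stats.chi2.sf(chi_sq, df)) if df > 0 else 1.0
    return float(chi_sq), int(df), p


# --------------------------------------------------------------------------
# permutation machinery (shared with the cluster engine)
# --------------------------------------------------------------------------

def within_group_permutations(
    group_codes: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) row-index permutations that shuffle only within groups.

    Exchanging labels within each subject preserves every subject's
    related/unrelated counts, so subject effects are ancillary under the
    permutation null.
    """
    group_codes = np.asarray(group_codes)
    n = len(group_codes)
    idx = np.tile(np.arange(n), (n_perm, 1))
    for g in np.unique(group_codes):
        pos = np.flatnonzero(group_codes == g)
        keys = rng.random((n_perm, len(pos)))
        order = np.argsort(keys, axis=1)
        idx[:, pos] = pos[order]
    return idx


def free_permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    keys = rng.random((n_perm, n))
    return np.argsort(keys, axis=1)


def batched_term_t(
    struct: GroupStructure,
    lam: tuple[float, float],
    B: np.ndarray,
    P: np.ndarray,
    y: np.ndarray,
    whiten=None,
) -> np.ndarray:
    """t-value of a permuted column appended to a fixed base design.

    For each column p_j of ``P`` the model is X_j = [B, p_j]; variance
    ratios are held at ``lam`` (score-type approximation) and the residual
    variance is re-profiled per permutation with an (n - p) denominator,
    matching the REML-reported observed t.  Returns (m,) t-values.
    """
    n, pb = B.shape
    sd, L, _ = whiten if whiten is not None else _whiten_factor(struct, *lam)[0:3]
    TB = solve_triangular(L, sd[:, None] * struct.Zt(B), lower=True)
    ty = solve_triangular(L, sd * struct.Zt(y), lower=True)
    TP = solve_triangular(L, sd[:, None] * struct.Zt(P), lower=True)
    BWB = B.T @ B - TB.T @ TB
    BWy = B.T @ y - TB.T @ ty
    yWy = float(y @ y - ty @ ty)
    BWP = B.T @ P - TB.T @ TP
    PWP = np.einsum("ij,ij->j", P, P) - np.einsum("ij,ij->j", TP, TP)
    PWy = P.T @ y - TP.T @ ty

    Ginv = np.linalg.inv(BWB)
    Gb = Ginv @ BWy
    GP = Ginv @ BWP  # (pb, m)
    schur = PWP - np.einsum("ij,ij->j", BWP, GP)
    schur = np.clip(schur, 1e-30, None)
    num = PWy - BWP.T @ Gb
    beta = num / schur
    base_rss = yWy - BWy @ Gb
    rss = np.clip(base_rss - num * beta, 1e-30, None)
    sigma2 = rss / (n - pb - 1)
    with np.errstate(invalid="ignore"):
        t = beta / np.sqrt(sigma2 / schur)
    return np.nan_to_num(t, nan=0.0)


def batched_interaction_chisq(
    struct: GroupStructure,
    lam: tuple[float, float],
    b: np.ndarray,
    P: np.ndarray,
    y: np.ndarray,
    whiten=None,
) -> np.ndarray:
    """ML likelihood-ratio chi^2 for the a x b interaction, batched over
    permuted ``a`` columns.

    Reduced model per permutation: [1, a_j, b]; full: [1, a_j, b, a_j*b].
    Variance ratios held at ``lam``; residual variance re-profiled (ML,
    denominator n) in both models, so chi^2 = n * log(RSS_red / RSS_full).
    """
    n = len(y)
    m = P.shape[1]
    ones = np.ones(n)
    F = np.column_stack([ones, b])  # fixed columns
    AB = P * b[:, None]
    sd, L, _ = whiten if whiten is not None else _whiten_factor(struct, *lam)[0:3]

    def wh(M):
        return solve_triangular(L, sd[:, None] * struct.Zt(M), lower=True)

    TF, ty, TP, TAB = wh(F), wh(y[:, None])[:, 0], wh(P), wh(AB)
    FWF = F.T @ F - TF.T @ TF
    FWy = F.T @ y - TF.T @ ty
    yWy = float(y @ y - ty @ ty)
    FWP = F.T @ P - TF.T @ TP          # (2, m)
    FWAB = F.T @ AB - TF.T @ TAB        # (2, m)
    PWP = np.einsum("ij,ij->j", P, P) - np.einsum("ij,ij->j", TP, TP)
    ABWAB = np.einsum("ij,ij->j", AB, AB) - np.einsum("ij,ij->j", TAB, TAB)
    PWAB = np.einsum("ij,ij->j", P, AB) - np.einsum("ij,ij->j", TP, TAB)
    PWy = P.T @ y - TP.T @ ty
    ABWy = AB.T @ y - TAB.T @ ty

    # reduced: design columns [F, p_j] -> 3x3 systems
    G3 = np.zeros((m, 3, 3))
    G3[:, :2, :2] = FWF
    G3[:, :2, 2] = FWP.T
    G3[:, 2, :2] = FWP.T
    G3[:, 2, 2] = PWP
    r3 = np.zeros((m, 3))
    r3[:, :2] = FWy
    r3[:, 2] = PWy
    sol3 = np.linalg.solve(G3 + 1e-12 * np.eye(3), r3[..., None])[..., 0]
    rss_red = np.clip(yWy - np.einsum("mj,mj->m", r3, sol3), 1e-30, None)

    # full: [F, p_j, (p*b)_j] -> 4x4 systems
    G4 = np.zeros((m, 4, 4))
    G4[:, :3, :3] = G3
    G4[:, :2, 3] = FWAB.T
    G4[:, 3, :2] = FWAB.T
    G4[:, 2, 3] = PWAB
    G4[:, 3, 2] = PWAB
    G4[:, 3, 3] = ABWAB
    r4 = np.zeros((m, 4))
    r4[:, :3] = r3
    r4[:, 3] = ABWy
    sol4 = np.linalg.solve(G4 + 1e-12 * np.eye(4), r4[..., None])[..., 0]
    rss_full = np.clip(yWy - np.einsum("mj,mj->m", r4, sol4), 1e-30, None)

    chi2 = n * (np.log(rss_red) - np.log(rss_full))
    return np.clip(chi2, 0.0, None)


def mc_pvalue_fixed_effect(
    trials: pd.DataFrame,
    term: str = "prime_type",
    response: str = "rt_ms",
    n_iter: int = 10000,
    seed: int | None = None,
    subject_col: str = "subject_id",
    item_col: str = "item_id",
    chunk: int = 2000,
) -> float:
    """Monte-Carlo p-value for a two-level fixed effect.

    The observed |t| (REML fit with crossed subject/item intercepts) is
    compared against ``n_iter`` within-subject relabelings of the term;
    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_iter), so p is in (0, 1]
    and never exactly zero.  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    df = trials.dropna(subset=[response])
    col, name = _term_column(df, term)
    if np.ptp(col) == 0:
        raise ValueError(f"term {term!r} is constant")
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), col])
    est = CrossedLMM(method="REML")
    est.fit(X, y, subjects=df[subject_col], items=df[item_col],
            term_names=["Intercept", name])
    t_obs = abs(est.tvalues_[1])
    struct = est.struct_
    lam = est.ratios_
    whiten = _whiten_factor(struct, *lam)
    rng = np.random.default_rng(seed)
    B = np.ones((n, 1))
    count = 0
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        idx = within_group_permutations(struct.si, m, rng)
        P = col[idx].T  # (n, m)
        t_perm = batched_term_t(struct, lam, B, P, y, whiten=whiten)
        count += int(np.sum(np.abs(t_perm) >= t_obs - 1e-12))
        done += m
    return (1.0 + count) / (1.0 + n_iter)
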