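"""Shared REML machinery for the variance-component models in the pipeline.

Three building blocks:

* :func:`eigen_reml` — restricted likelihood for ``y = X b + g + e`` with
  ``g ~ N(0, s2_g K)``, maximized over the variance ratio
  ``delta = s2_e / s2_g`` on a fixed eigendecomposition of K (the
  EMMA-style computation reused across GWAS steps and GBLUP fits).
* :func:`reml_oneway` — REML for a single iid random factor partitioning
  the observations (``y = X b + Z u + e``), via the profiled restricted
  likelihood of the ratio ``gamma = s2_u / s2_e`` using groupwise Woodbury
  identities; reduces exactly to the balanced ANOVA estimators when the
  design is balanced.
* :func:`mme_reml` — generic dense mixed-model-equation REML for several
  iid (or diagonally penalized) random blocks, maximized over log variance
  ratios by a coarse grid followed by Nelder-Mead; used by the spatial
  P-spline model.

All objective functions are deterministic; optimizers use fixed bounds and
tolerances, never random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

LOG_RATIO_BOUNDS = (-10.0, 10.0)
CHI2_1_95 = 3.8414588206941236  # scipy.stats.chi2.ppf(0.95, 1)


# ------------------------------------------------------- EMMA-style REML

def _neg2_loglik_restricted(log_delta: float, lam: np.ndarray, Uty: np.ndarray,
                            UtX: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    XtWX = UtX.T @ (UtX * w[:, None])
    XtWy = UtX.T @ (w * Uty)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = Uty - UtX @ beta
    n, p = UtX.shape
    rss = float(np.sum(w * resid**2))
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    return ((n - p) * np.log(rss) + np.sum(np.log(lam + delta)) + logdet_XtWX)


@dataclass
class EigenRemlFit:
    delta: float            # s2_e / s2_g
    s2_g: float
    s2_e: float
    beta: np.ndarray
    neg2_loglik: float
    lam: np.ndarray
    Uty: np.ndarray
    UtX: np.ndarray

    def gls(self, UtS: np.ndarray):
        """Wald tests of extra columns (one at a time) added to the design.

        ``UtS`` is (n, m) of rotated candidate columns; returns (beta_hat,
        se, p_value) arrays of length m, computed jointly with the current
        fixed effects at the fitted delta. Columns collinear with the
        current design give NaN.
        """
        from scipy import stats

        w = 1.0 / (self.lam + self.delta)
        X, y = self.UtX, self.Uty
        n, p = X.shape
        A = X.T @ (X * w[:, None])
        Ainv = np.linalg.inv(A)
        Xty = X.T @ (w * y)
        StWS = np.sum(UtS**2 * w[:, None], axis=0)
        StWX = (UtS * w[:, None]).T @ X            # (m, p)
        StWy = UtS.T @ (w * y)
        # Schur complement of the bordered normal equations per column
        t1 = StWX @ Ainv                            # (m, p)
        s_schur = StWS - np.sum(t1 * StWX, axis=1)  # (m,)
        with np.errstate(divide="ignore", invalid="ignore"):
            bhat = (StWy - t1 @ Xty) / s_schur
        base_beta = Ainv @ Xty
        resid0 = y - X @ base_beta
        rss0 = float(np.sum(w * resid0**2))
        rss = rss0 - bhat**2 * s_schur
        dof = n - p - 1
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 / s_schur)
            tstat = bhat / se
        pvals = 2 * stats.t.sf(np.abs(tstat), dof)
        bad = ~np.isfinite(tstat) | (s_schur <= max(1e-8 * np.max(StWS, initial=1.0), 1e-12))
        pvals[bad] = np.nan
        return bhat, se, pvals


def eigen_reml(y: np.ndarray, X: np.ndarray, lam: np.ndarray, U: np.ndarray,
               tol: float = 1e-6) -> EigenRemlFit:
    """REML fit of a single-kernel mixed model on a precomputed spectrum.

    ``lam``/``U`` are the eigenvalues/vectors of the covariance kernel K.
    The ratio ``delta`` is found by bounded scalar minimization of the
    restricted likelihood over ``log delta`` in [-10, 10].
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    Uty = U.T @ y
    UtX = U.T @ X
    res = optimize.minimize_scalar(
        _neg2_loglik_restricted, bounds=LOG_RATIO_BOUNDS, method="bounded",
        args=(lam, Uty, UtX), options={"xatol": tol},
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (lam + delta)
    XtWX = UtX.T @ (UtX * w[:, None])
    beta = np.linalg.solve(XtWX, UtX.T @ (w * Uty))
    resid = Uty - UtX @ beta
    n, p = UtX.shape
    s2_g = float(np.sum(w * resid**2) / (n - p))
    return EigenRemlFit(delta=delta, s2_g=s2_g, s2_e=s2_g * delta, beta=beta,
                        neg2_loglik=float(res.fun), lam=lam, Uty=Uty, UtX=UtX)


# ------------------------------------------------- one-way (partition) REML

@dataclass
class OnewayFit:
    s2_u: float
    s2_e: float
    beta: np.ndarray
    blups: np.ndarray           # one BLUP per group, group order
    group_labels: list
    neg2_loglik: float
    n: int
    p: int


def _oneway_profile(log_gamma: float, y, X, gidx, gsizes) -> tuple[float, np.ndarray, float]:
    """Profiled -2 restricted log-likelihood for the ratio gamma = s2_u/s2_e.

    Uses V0 = I + gamma Z Z^T with Z a partition indicator, inverted
    groupwise: V0^-1 = I - diag_g(gamma / (1 + gamma n_g)) within groups.
    Returns (-2 l_R up to constant, GLS beta, profiled s2_e).
    """
    gamma = np.exp(log_gamma)
    shrink = gamma / (1.0 + gamma * gsizes)          # per group
    n, p = X.shape

    def v0inv_dot(M):
        # V0^{-1} M  for column(s) M
        M = np.atleast_2d(M.T).T
        gsum = np.zeros((len(gsizes), M.shape[1]))
        np.add.at(gsum, gidx, M)
        return M - shrink[gidx, None] * gsum[gidx]

    ViX = v0inv_dot(X)
    Viy = v0inv_dot(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    ytPy = float(r @ v0inv_dot(r[:, None])[:, 0])
    s2_e = ytPy / (n - p)
    logdetV0 = float(np.sum(np.log1p(gamma * gsizes)))
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    neg2 = (n - p) * np.log(ytPy) + logdetV0 + logdet_XtViX
    return neg2, beta, s2_e


def reml_oneway(y: np.ndarray, X: np.ndarray, groups, tol: float = 1e-10
                ) -> OnewayFit:
    """REML for one iid random factor (partition) plus fixed effects.

    The boundary s2_u = 0 is checked explicitly: if the profiled likelihood
    at the lower ratio bound beats the interior optimum, the variance is
    reported as exactly 0.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    labels, gidx = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    gsizes = np.bincount(gidx).astype(float)
    n, p = X.shape
    if len(labels) < 2:
        raise ValueError("need >= 2 groups to separate group variance from error")
    if np.all(gsizes == 1):
        raise ValueError("all-singleton groups: group variance unidentifiable")

    obj = lambda lg: _oneway_profile(lg, y, X, gidx, gsizes)[0]
    lo, hi = -25.0, 15.0
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    lg = float(res.x)
    # boundary check: gamma -> 0 (pure error model)
    if obj(lo) <= res.fun + 1e-12 or lg <= lo + 1e-6:
        lg = -np.inf
        gamma = 0.0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2_e = float(r @ r / (n - p))
        s2_u = 0.0
        neg2 = (n - p) * np.log(r @ r) + np.linalg.slogdet(X.T @ X)[1]
    else:
        gamma = float(np.exp(lg))
        neg2, beta, s2_e = _oneway_profile(lg, y, X, gidx, gsizes)
        s2_u = gamma * s2_e
    # BLUPs: shrunken group means of GLS residuals
    r = y - X @ beta
    gsum = np.zeros(len(labels))
    np.add.at(gsum, gidx, r)
    shrink = gamma * gsizes / (1.0 + gamma * gsizes) if gamma > 0 else np.zeros_like(gsizes)
    blups = shrink * gsum / np.maximum(gsizes, 1)
    # note: for one-way partition, BLUP = (gamma n_g/(1+gamma n_g)) * mean resid
    return OnewayFit(s2_u=s2_u, s2_e=s2_e, beta=beta, blups=blups,
                     group_labels=list(labels), neg2_loglik=float(neg2), n=n, p=p)


def oneway_neg2_profile(y, X, groups):
    """Return a callable -2 l_R(gamma-ratio path) helper for profile CIs."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    labels, gidx = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    gsizes = np.bincount(gidx).astype(float)
    return lambda log_gamma: _oneway_profile(log_gamma, y, X, gidx, gsizes)


# ---------------------------------------------------- generic dense MME REML

@dataclass
class MmeFit:
    beta: np.ndarray
    u: list[np.ndarray]          # per random block
    ratios: np.ndarray           # precision ratios actually used (log scale input)
    s2_e: float
    neg2_loglik: float
    eff_dims: list[float]
    fitted: np.ndarray
    Cinv: np.ndarray


def mme_reml(y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray],
             penalties: list, *, coarse: np.ndarray | None = None,
             maxiter: int = 400) -> MmeFit:
    """REML over several random blocks via dense mixed-model equations.

    ``penalties`` holds, per block, either the string "iid" (one unknown
    ratio) or a tuple of nonnegative diagonal penalty generators
    ``(d1, d2, ...)`` combined as ``r1*d1 + r2*d2`` with unknown ratios —
    used for the anisotropic tensor P-spline penalty. The profiled
    restricted likelihood is minimized over all log ratios, initialized
    from a coarse grid and refined with Nelder-Mead.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    blocks = []
    n_par = 0
    for Z, pen in zip(Zs, penalties):
        if pen == "iid":
            blocks.append(("iid", Z, None))
            n_par += 1
        else:
            blocks.append(("diag", Z, [np.asarray(d, float) for d in pen]))
            n_par += len(pen)
    W = np.column_stack([X] + [b[1] for b in blocks])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    sizes = [X.shape[1]] + [b[1].shape[1] for b in blocks]
    offs = np.cumsum([0] + sizes)

    def lam_diag(theta):
        """Full penalty diagonal (length total random dim) and log|Lambda|."""
        diag = np.zeros(offs[-1] - p)
        logdet = 0.0
        ti = 0
        for bi, (kind, Z, dgen) in enumerate(blocks):
            q = Z.shape[1]
            sl = slice(offs[bi + 1] - p, offs[bi + 2] - p)
            if kind == "iid":
                r = np.exp(theta[ti]); ti += 1
                diag[sl] = r
                logdet += q * theta[ti - 1]
            else:
                d = np.zeros(q)
                for dg in dgen:
                    d += np.exp(theta[ti]) * dg
                    ti += 1
                diag[sl] = d
                logdet += float(np.sum(np.log(d)))
        return diag, logdet

    def neg2(theta):
        diag, logdet_lam = lam_diag(theta)
        C = WtW.copy()
        C[p:, p:] += np.diag(diag)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return 1e12
        sol = np.linalg.solve(L, Wty)
        ytPy = yty - float(sol @ sol)
        if ytPy <= 0:
            return 1e12
        logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
        return (n - p) * np.log(ytPy) + logdetC - logdet_lam

    if coarse is None:
        coarse = np.array([-2.0, 1.0, 4.0])
    best, best_val = None, np.inf
    grid = np.meshgrid(*([coarse] * n_par), indexing="ij")
    for combo in np.stack([g.ravel() for g in grid], axis=1):
        v = neg2(combo)
        if v < best_val:
            best, best_val = combo, v
    res = optimize.minimize(neg2, best, method="Nelder-Mead",
                            options={"maxiter": maxiter * n_par, "xatol": 1e-4,
                                     "fatol": 1e-7})
    theta = res.x
    diag, _ = lam_diag(theta)
    C = WtW.copy()
    C[p:, p:] += np.diag(diag)
    Cinv = np.linalg.inv(C)
    coef = Cinv @ Wty
    ytPy = yty - float(Wty @ coef)
    s2_e = ytPy / (n - p)
    beta = coef[:p]
    u = [coef[offs[i + 1]:offs[i + 2]] for i in range(len(blocks))]
    eff_dims = []
    for bi, (kind, Z, dgen) in enumerate(blocks):
        sl = slice(offs[bi + 1], offs[bi + 2])
        lam_b = diag[offs[bi + 1] - p: offs[bi + 2] - p]
        eff_dims.append(float(Z.shape[1] - np.sum(lam_b * np.diag(Cinv)[sl])))
    fitted = W @ coef
    return MmeFit(beta=beta, u=u, ratios=theta, s2_e=s2_e,
                  neg2_loglik=float(res.fun), eff_dims=eff_dims,
                  fitted=fitted, Cinv=Cinv)
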