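"""Phenotypic analyses: spatial adjustment, heritability, LS-means.

Per environment, raw tree values are corrected for spatial field
heterogeneity with a mixed model containing a penalized tensor-product
cubic B-spline surface over (row, column) plus random genotype, random row
and random column effects:

    y = f(u, v) + Z_g c_g + Z_r c_r + Z_c c_c + e

The full PS-ANOVA decomposition of the smooth into five subcomponents is
simplified to a single anisotropic tensor penalty with two smoothing
parameters (one per axis); effective dimensions are reported for the
combined smooth and each random factor. The adjusted value of a tree is
the predicted genotype value (intercept + genotype BLUP; smooth, row and
column terms excluded) plus the tree's residual.

Clonal-mean heritability uses the one-way REML variance components:
individual-location H2 = s2_g / (s2_g + s2_e / n_r) and multi-location
H2 = s2_g / (s2_g + s2_gl / n_l + s2_e / (n_l n_r)). Environments whose
individual-location H2 falls below a threshold (default 0.1) are excluded
before the pooled analysis. LS-means come from the additive two-way fixed
model y = mu + g_i + l_j + e via ordinary least squares, averaging the
cell predictions of each genotype over all retained environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline

from .datamodel import TreeRecordTable
from .mixedlm import CHI2_1_95, mme_reml, reml_oneway


# --------------------------------------------------------------- B-splines

def _bspline_basis(x: np.ndarray, knot_spacing: float = 4.0, degree: int = 3
                   ) -> np.ndarray:
    """Cubic B-spline design matrix with equally spaced knots over x's range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1.0)
    n_seg = max(int(np.ceil(span / knot_spacing)), 2)
    inner = np.linspace(lo, hi, n_seg + 1)
    h = inner[1] - inner[0]
    t = np.concatenate([lo - h * np.arange(degree, 0, -1), inner,
                        hi + h * np.arange(1, degree + 1)])
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def _margin_decomposition(B: np.ndarray):
    """Split a marginal B-spline basis into polynomial null space and
    penalized directions of the second-order difference penalty.

    The null space of D2'D2 is spanned by coefficient vectors constant and
    linear in the coefficient index (for equally spaced knots these map to
    the functions 1 and x). Returns (T_null (n,2), T_pen (n,k-2),
    eigenvalues of the penalized directions).
    """
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    w, U = np.linalg.eigh(D.T @ D)
    pen = w > 1e-10
    idx = np.arange(k, dtype=float)
    null_coefs = np.column_stack([np.ones(k), (idx - idx.mean()) / k])
    return B @ null_coefs, B @ U[:, pen], np.maximum(w[pen], 0.0)


def _penalized_tensor(Bu: np.ndarray, Bv: np.ndarray):
    """Transformed tensor basis with diagonal anisotropic penalty.

    Returns (X_null, Z_smooth, d_u, d_v): fixed null-space columns
    (u, v, u*v; the constant is excluded as collinear with the model
    intercept), penalized random columns, and the two diagonal penalty
    generators such that the smooth precision is
    ``lambda_u * d_u + lambda_v * d_v``.
    """
    Nu, Pu, wu = _margin_decomposition(Bu)
    Nv, Pv, wv = _margin_decomposition(Bv)

    def rk(A, B):
        return (A[:, :, None] * B[:, None, :]).reshape(len(A), -1)

    X_null = np.column_stack([Nu[:, 1], Nv[:, 1], Nu[:, 1] * Nv[:, 1]])
    Z_blocks, du, dv = [], [], []
    # null_u x pen_v: penalized in v only
    Z_blocks.append(rk(Nu, Pv))
    du.append(np.zeros(2 * len(wv)))
    dv.append(np.tile(wv, 2))
    # pen_u x null_v: penalized in u only
    Z_blocks.append(rk(Pu, Nv))
    du.append(np.repeat(wu, 2))
    dv.append(np.zeros(2 * len(wu)))
    # pen_u x pen_v
    Z_blocks.append(rk(Pu, Pv))
    du.append(np.repeat(wu, len(wv)))
    dv.append(np.tile(wv, len(wu)))
    return (X_null, np.column_stack(Z_blocks),
            np.concatenate(du), np.concatenate(dv))


# ------------------------------------------------------------- spatial fit

@dataclass
class SpatialFit:
    environment: str
    trait: str
    intercept: float
    genotype_effects: dict[str, float]
    surface: np.ndarray          # fitted smooth value per tree (incl. null-space part)
    spatial_total: np.ndarray    # smooth + row + column contributions per tree
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    effective_dims: dict[str, float]
    smoothing: dict[str, float]
    s2_e: float
    notes: list[str] = field(default_factory=list)


def spatial_adjust(trees: TreeRecordTable, environment: str, trait: str | None = None,
                   knot_spacing: float = 4.0) -> tuple[SpatialFit, TreeRecordTable]:
    """Spatially adjust one environment (one trait) of tree-level data.

    Returns the fit and a table of the same shape whose values are
    ``intercept + genotype BLUP + residual``. Layouts without enough
    distinct rows (or columns) for a 2D surface degrade to a 1D smooth
    with a warning recorded in ``fit.notes``.
    """
    df = trees.df[trees.df["environment"] == environment]
    if trait is None:
        traits = list(dict.fromkeys(df["trait"]))
        if len(traits) != 1:
            raise ValueError("multiple traits present; pass trait=")
        trait = traits[0]
    df = df[df["trait"] == trait].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no records for environment {environment!r}, trait {trait!r}")
    y = df["value"].to_numpy(float)
    u = df["row"].to_numpy(float)
    v = df["col"].to_numpy(float)
    n = len(y)
    notes: list[str] = []

    glabels, gidx = np.unique(df["genotype"], return_inverse=True)
    Zg = np.zeros((n, len(glabels)))
    Zg[np.arange(n), gidx] = 1.0

    # degenerate input: replicates already identical within genotype, the
    # genotype-mean model fits exactly -> nothing to adjust
    gmeans = np.bincount(gidx, weights=y) / np.bincount(gidx)
    if float(np.sum((y - gmeans[gidx]) ** 2)) <= 1e-12 * max(float(np.var(y)), 1e-12) * n:
        mu = float(y.mean())
        zero = np.zeros(n)
        sf = SpatialFit(environment=environment, trait=trait, intercept=mu,
                        genotype_effects=dict(zip(glabels, gmeans - mu)),
                        surface=zero, spatial_total=zero,
                        row_effects=np.zeros(0), col_effects=np.zeros(0),
                        residuals=zero, effective_dims={"genotype": float(len(glabels) - 1)},
                        smoothing={}, s2_e=0.0,
                        notes=["exact genotype fit; spatial model skipped"])
        return sf, TreeRecordTable(df.copy())
    rlabels, ridx = np.unique(u, return_inverse=True)
    clabels, cidx = np.unique(v, return_inverse=True)
    Zr = np.zeros((n, len(rlabels)))
    Zr[np.arange(n), ridx] = 1.0
    Zc = np.zeros((n, len(clabels)))
    Zc[np.arange(n), cidx] = 1.0

    two_d = len(rlabels) >= 5 and len(clabels) >= 5
    X_cols = [np.ones(n)]
    if two_d:
        Bu = _bspline_basis(u, knot_spacing)
        Bv = _bspline_basis(v, knot_spacing)
        Xn, Zs, du, dv = _penalized_tensor(Bu, Bv)
        X_cols.append(Xn)
        smooth_pen = (du, dv)
    else:
        axis = u if len(rlabels) >= 5 else v
        notes.append("layout rank-deficient for a 2D surface; fitted 1D smooth")
        warnings.warn(notes[-1], stacklevel=2)
        B = _bspline_basis(axis, knot_spacing)
        Nn, Pn, w = _margin_decomposition(B)
        X_cols.append(Nn[:, [1]])  # linear term; constant covered by intercept
        Zs = Pn
        smooth_pen = (w,)
    X = np.column_stack(X_cols)
    n_null = X.shape[1] - 1

    Zs_list = [Zg, Zr, Zc, Zs]
    pens: list = ["iid", "iid", "iid", smooth_pen]
    fit = mme_reml(y, X, Zs_list, pens)

    intercept = float(fit.beta[0])
    g_eff = dict(zip(glabels, fit.u[0]))
    surface = X[:, 1:] @ fit.beta[1:] + Zs @ fit.u[3]
    spatial_total = surface + Zr @ fit.u[1] + Zc @ fit.u[2]
    residuals = y - fit.fitted
    adj = intercept + fit.u[0][gidx] + residuals

    out = df.copy()
    out["value"] = adj
    eff = {
        "genotype": fit.eff_dims[0], "row": fit.eff_dims[1],
        "col": fit.eff_dims[2], "smooth": fit.eff_dims[3],
        "fixed_null_space": float(n_null),
    }
    smoothing = {f"log_ratio_{i}": float(t) for i, t in enumerate(fit.ratios)}
    sf = SpatialFit(environment=environment, trait=trait, intercept=intercept,
                    genotype_effects=g_eff, surface=surface,
                    spatial_total=spatial_total,
                    row_effects=fit.u[1], col_effects=fit.u[2],
                    residuals=residuals, effective_dims=eff,
                    smoothing=smoothing, s2_e=fit.s2_e, notes=notes)
    return sf, TreeRecordTable(out)


def spatial_adjust_all(trees: TreeRecordTable, knot_spacing: float = 4.0
                       ) -> tuple[dict[tuple[str, str], SpatialFit], TreeRecordTable]:
    """Adjust every (trait, environment) combination; concatenated output."""
    fits: dict[tuple[str, str], SpatialFit] = {}
    parts = []
    for trait in trees.traits():
        sub = TreeRecordTable(trees.for_trait(trait))
        for env in sub.environments():
            f, adj = spatial_adjust(sub, env, trait, knot_spacing)
            fits[(trait, env)] = f
            parts.append(adj.df)
    return fits, TreeRecordTable(pd.concat(parts, ignore_index=True))


# ----------------------------------------------------------- heritability

def individual_h2(s2_g: float, s2_e: float, n_rep: float) -> tuple[float, float]:
    """(phenotypic variance, H2) for a single location: s2_p = s2_g + s2_e/n_rep."""
    s2_p = s2_g + s2_e / n_rep
    return s2_p, (s2_g / s2_p if s2_p > 0 else 0.0)


def multi_location_h2(s2_g: float, s2_gl: float, s2_e: float, n_loc: int,
                      n_rep: float) -> tuple[float, float]:
    """(phenotypic variance, H2) across locations:
    s2_p = s2_g + s2_gl/n_loc + s2_e/(n_loc * n_rep)."""
    s2_p = s2_g + s2_gl / n_loc + s2_e / (n_loc * n_rep)
    return s2_p, (s2_g / s2_p if s2_p > 0 else 0.0)


@dataclass
class HeritabilityResult:
    context: str                 # "individual-location" | "multi-location"
    s2_g: float
    s2_e: float
    n_rep: float
    s2_p: float
    H2: float
    s2_gl: float | None = None
    n_loc: int | None = None
    environment: str | None = None
    trait: str | None = None


def h2_individual(trees: TreeRecordTable, environment: str | None = None,
                  trait: str | None = None) -> HeritabilityResult:
    """Individual-location clonal-mean heritability via one-way REML.

    H2 = s2_g / (s2_g + s2_e / n_r) with n_r the arithmetic mean number of
    replicate trees per genotype.
    """
    df = trees.df
    if environment is not None:
        df = df[df["environment"] == environment]
    if trait is not None:
        df = df[df["trait"] == trait]
    if df.empty:
        raise ValueError("no records selected")
    y = df["value"].to_numpy(float)
    fit = reml_oneway(y, np.ones((len(y), 1)), df["genotype"].to_numpy())
    n_rep = float(df.groupby("genotype").size().mean())
    s2_p, h2 = individual_h2(fit.s2_u, fit.s2_e, n_rep)
    return HeritabilityResult(
        context="individual-location", s2_g=fit.s2_u, s2_e=fit.s2_e,
        n_rep=n_rep, s2_p=s2_p, H2=h2,
        environment=environment, trait=trait,
    )


def exclude_low_h2(results: dict[str, HeritabilityResult], threshold: float = 0.1
                   ) -> list[str]:
    """Environments whose individual-location H2 passes the threshold."""
    keep = [env for env, r in results.items() if r.H2 >= threshold]
    if not keep:
        raise ValueError("all environments fall below the heritability threshold")
    return keep


# ------------------------------------------------- multi-environment model

@dataclass
class VarianceDecomposition:
    fractions: dict[str, float]          # environment (fixed), genotype, gxe, residual
    variances: dict[str, float]
    confidence_intervals: dict[str, tuple[float, float]]
    total_variance: float


def _multienv_neg2(df_cells: pd.DataFrame, ssw: float, dfw: int, k: float,
                   X: np.ndarray, gidx: np.ndarray, gsizes: np.ndarray):
    """-2 restricted log-likelihood of (s2_g, s2_gl, s2_e), factorized form.

    Valid for equal replication k per genotype-environment cell: within-cell
    contrasts carry s2_e alone; cell means follow a one-way model with
    genotype variance s2_g and cell noise tau2 = s2_gl + s2_e / k.
    """
    ybar = df_cells["value"].to_numpy(float)
    n_cells, p = X.shape

    def neg2(s2_g, s2_gl, s2_e):
        if s2_e <= 0 or s2_g < 0 or s2_gl < 0:
            return np.inf
        tau2 = s2_gl + s2_e / k
        gamma = s2_g / tau2
        shrink = gamma / (1.0 + gamma * gsizes)

        def vinv(M):
            M = np.atleast_2d(M.T).T
            gsum = np.zeros((len(gsizes), M.shape[1]))
            np.add.at(gsum, gidx, M)
            return M - shrink[gidx, None] * gsum[gidx]

        ViX = vinv(X)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ vinv(ybar[:, None])[:, 0])
        r = ybar - X @ beta
        ytPy = float(r @ vinv(r[:, None])[:, 0])
        logdetV0 = float(np.sum(np.log1p(gamma * gsizes)))
        _, logdet_XtViX = np.linalg.slogdet(XtViX)
        cell_part = ((n_cells - p) * np.log(tau2) + logdetV0 + logdet_XtViX
                     + ytPy / tau2)
        within_part = dfw * np.log(s2_e) + ssw / s2_e
        return cell_part + within_part

    return neg2


def fit_multienv(adjusted: TreeRecordTable, trait: str | None = None,
                 ci_level: float = 0.95, compute_ci: bool = True
                 ) -> tuple[VarianceDecomposition, HeritabilityResult]:
    """Pooled multi-environment analysis of (spatially adjusted) tree values.

    Model: value = mu + env (fixed) + genotype (random) + genotype x env
    (random) + error. Requires equal replication per genotype-environment
    cell (complete blocks). Returns the variance decomposition — the fixed
    environment fraction is the variance of predictions with all random
    effects zeroed over the total — and multi-location clonal-mean
    heritability. Profile-likelihood CIs (chi2_1 cutoff) are reported for
    each random-component variance.
    """
    df = adjusted.df
    if trait is not None:
        df = df[df["trait"] == trait]
    envs = sorted(set(df["environment"]))
    if len(envs) < 2:
        raise ValueError("multi-environment analysis needs >= 2 environments")
    counts = df.groupby(["genotype", "environment"]).size()
    k_vals = counts.unique()
    if len(k_vals) != 1:
        raise ValueError(
            f"unequal replication per genotype x environment cell: {sorted(k_vals)}"
        )
    k = int(k_vals[0])
    if k < 2:
        raise ValueError("need >= 2 replicates per cell to separate error from G x E")

    cell = df.groupby(["genotype", "environment"], as_index=False)["value"].mean()
    ssw = float(((df["value"] - df.groupby(["genotype", "environment"])["value"]
                  .transform("mean")) ** 2).sum())
    dfw = len(df) - len(cell)
    s2_e = ssw / dfw

    env_labels, eidx = np.unique(cell["environment"], return_inverse=True)
    X = np.zeros((len(cell), len(env_labels)))
    X[np.arange(len(cell)), eidx] = 1.0           # cell-mean design: env means
    glabels, gidx = np.unique(cell["genotype"], return_inverse=True)
    gsizes = np.bincount(gidx).astype(float)

    ow = reml_oneway(cell["value"].to_numpy(float), X, cell["genotype"].to_numpy())
    tau2 = ow.s2_e
    s2_g = ow.s2_u
    s2_gl = max(tau2 - s2_e / k, 0.0)

    n_l = len(envs)
    n_rep = float(k)
    s2_p, h2v = multi_location_h2(s2_g, s2_gl, s2_e, n_l, n_rep)
    h2 = HeritabilityResult(
        context="multi-location", s2_g=s2_g, s2_e=s2_e, n_rep=n_rep,
        s2_p=s2_p, H2=h2v, s2_gl=s2_gl,
        n_loc=n_l, trait=trait,
    )

    # fixed-effect fraction: variance of predictions with all random effects
    # zeroed, i.e. each tree predicted by its environment mean
    env_of_tree = pd.Categorical(df["environment"], categories=list(env_labels)).codes
    fixed_pred = ow.beta[env_of_tree]
    var_fixed = float(np.var(fixed_pred))
    total = var_fixed + s2_g + s2_gl + s2_e
    fractions = {
        "environment": var_fixed / total,
        "genotype": s2_g / total,
        "gxe": s2_gl / total,
        "residual": s2_e / total,
    }
    variances = {"environment_fixed": var_fixed, "genotype": s2_g,
                 "gxe": s2_gl, "residual": s2_e}

    cis: dict[str, tuple[float, float]] = {}
    if compute_ci:
        neg2 = _multienv_neg2(cell, ssw, dfw, k, X, gidx, gsizes)
        mle = {"genotype": s2_g, "gxe": s2_gl, "residual": s2_e}
        base = neg2(s2_g, s2_gl, s2_e)
        cutoff = CHI2_1_95 if abs(ci_level - 0.95) < 1e-9 else float(
            __import__("scipy.stats", fromlist=["chi2"]).chi2.ppf(ci_level, 1))

        def profiled(name, val):
            def obj(logother):
                a, b = np.exp(logother)
                args = {"genotype": (val, a, b), "gxe": (a, val, b),
                        "residual": (a, b, val)}[name]
                return neg2(*args)
            others = [v for nm, v in mle.items() if nm != name]
            x0 = np.log(np.maximum(others, 1e-6))
            res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-9})
            return res.fun

        for name, vhat in mle.items():
            scale = max(vhat, s2_e, 1e-8)
            lr = lambda v: profiled(name, max(v, 0.0)) - base - cutoff
            # lower bound
            if lr(0.0 if name != "residual" else scale * 1e-6) < 0:
                lo_b = 0.0
            else:
                lo_b = _bisect(lr, 1e-12 if name == "residual" else 0.0, vhat, 1e-6)
            # upper bound
            hi = vhat + scale
            while lr(hi) < 0 and hi < vhat + 1e4 * scale:
                hi = vhat + (hi - vhat) * 2
            hi_b = _bisect(lambda v: -lr(v), vhat, hi, 1e-6)
            cis[name] = (lo_b, hi_b)

    vd = VarianceDecomposition(fractions=fractions, variances=variances,
                               confidence_intervals=cis, total_variance=total)
    return vd, h2


def _bisect(f, lo, hi, tol):
    """Root of sign change of f on [lo, hi] (f(lo) <= 0 <= f(hi) or reverse)."""
    flo = f(lo)
    for _ in range(200):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        if (f(mid) <= 0) == (flo <= 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------- LS-means

def ls_means(adjusted: TreeRecordTable, environments: list[str] | None = None,
             trait: str | None = None) -> pd.DataFrame:
    """Genotype LS-means across environments from the additive two-way OLS fit.

    LS-mean of genotype i = mean over all retained environments j of
    (mu + g_i + l_j). Requires a connected genotype x environment design.
    """
    df = adjusted.df
    if trait is not None:
        df = df[df["trait"] == trait]
    traits = list(dict.fromkeys(df["trait"]))
    out = []
    for tr in traits:
        sub = df[df["trait"] == tr]
        if environments is not None:
            sub = sub[sub["environment"].isin(environments)]
        envs = sorted(set(sub["environment"]))
        _check_connected(sub)
        glabels, gidx = np.unique(sub["genotype"], return_inverse=True)
        elabels, eidx = np.unique(sub["environment"], return_inverse=True)
        n = len(sub)
        # treatment coding, first level dropped for each factor
        X = np.ones((n, 1 + len(glabels) - 1 + len(elabels) - 1))
        X[:, 1:len(glabels)] = (gidx[:, None] == np.arange(1, len(glabels))[None, :])
        X[:, len(glabels):] = (eidx[:, None] == np.arange(1, len(elabels))[None, :])
        beta, *_ = np.linalg.lstsq(X, sub["value"].to_numpy(float), rcond=None)
        mu = beta[0]
        g = np.concatenate([[0.0], beta[1:len(glabels)]])
        l = np.concatenate([[0.0], beta[len(glabels):]])
        lsm = mu + g + l.mean()
        out.append(pd.DataFrame({"genotype": glabels, "trait": tr, "lsmean": lsm}))
    return pd.concat(out, ignore_index=True)


def _check_connected(df: pd.DataFrame) -> None:
    g = nx.Graph()
    for geno, env in df[["genotype", "environment"]].itertuples(index=False):
        g.add_edge(("g", geno), ("e", env))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        names = [sorted(x[1] for x in c if x[0] == "g")[:3] for c in comps]
        raise ValueError(f"disconnected genotype x environment design: {names}")
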