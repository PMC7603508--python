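"""RR-BLUP genomic prediction with repeated k-fold cross-validation.

Model: y = 1 mu + G u + e with u ~ N(0, I s2_u), e ~ N(0, I s2_e), where G
holds centered marker dosages and y one phenotypic LS-mean per genotype
(the design matrix relating genotypes to phenotypes is the identity).
Variance components come from spectral REML on the equivalent GBLUP model
(eigendecomposition of G G^T); marker effects solve the mixed-model
equations, via the n x n dual form when markers outnumber individuals.
Predictive ability is the Pearson correlation between observed and
predicted values in held-out folds, averaged per fold within a repetition
and then over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypePanel
from .mixedlm import eigen_reml


@dataclass
class RrBlupModel:
    mu: float
    u: np.ndarray                 # marker effects
    s2_u: float
    s2_e: float
    lam: float                    # ridge parameter s2_e / s2_u
    center: np.ndarray            # 2 * allele frequency used for centering

    def predict(self, dosage: np.ndarray) -> np.ndarray:
        return self.mu + (np.asarray(dosage, float) - self.center) @ self.u


def fit_rrblup(G: np.ndarray, y: np.ndarray, lam: float | None = None,
               center: bool = True) -> RrBlupModel:
    """Fit RR-BLUP via the dual (individual x individual) form.

    ``G`` holds raw dosages when ``center=True`` (centered internally by
    twice the allele frequency) or pre-centered values otherwise. With
    ``lam=None`` the ridge parameter is estimated by spectral REML;
    passing ``lam`` fixes it (used in oracle tests).
    """
    G = np.asarray(G, float)
    y = np.asarray(y, float)
    n, m = G.shape
    c = G.mean(axis=0) if center else np.zeros(m)
    Gc = G - c
    Kp = Gc @ Gc.T
    ones = np.ones((n, 1))
    if lam is None:
        lamv, U = np.linalg.eigh(Kp)
        lamv = np.maximum(lamv, 0.0)
        fit = eigen_reml(y, ones, lamv, U)
        lam = fit.delta
        mu = float(fit.beta[0])
        s2_u, s2_e = fit.s2_g, fit.s2_e
    else:
        Vi = np.linalg.inv(Kp + lam * np.eye(n))
        mu = float((ones[:, 0] @ Vi @ y) / (ones[:, 0] @ Vi @ ones[:, 0]))
        s2_u, s2_e = np.nan, np.nan
    alpha = np.linalg.solve(Kp + lam * np.eye(n), y - mu)
    u = Gc.T @ alpha
    return RrBlupModel(mu=mu, u=u, s2_u=s2_u, s2_e=s2_e, lam=float(lam), center=c)


def fit_rrblup_primal(G: np.ndarray, y: np.ndarray, lam: float,
                      center: bool = False) -> RrBlupModel:
    """Direct (marker x marker) mixed-model-equation solve; small cases only.

    [[n, 1'G], [G'1, G'G + lam I]] [mu; u] = [1'y; G'y]
    """
    G = np.asarray(G, float)
    y = np.asarray(y, float)
    n, m = G.shape
    c = G.mean(axis=0) if center else np.zeros(m)
    Gc = G - c
    C = np.empty((1 + m, 1 + m))
    C[0, 0] = n
    C[0, 1:] = Gc.sum(axis=0)
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = Gc.T @ Gc + lam * np.eye(m)
    rhs = np.concatenate([[y.sum()], Gc.T @ y])
    sol = np.linalg.solve(C, rhs)
    return RrBlupModel(mu=float(sol[0]), u=sol[1:], s2_u=np.nan, s2_e=np.nan,
                       lam=float(lam), center=c)


@dataclass
class CvResult:
    fold_assignments: np.ndarray      # (repetitions, n) fold index per genotype
    per_fold_ability: np.ndarray      # (repetitions, folds)
    per_repetition_ability: np.ndarray
    mean_ability: float
    pooled_ability_per_rep: np.ndarray  # alternative: r pooled over folds
    folds: int
    repetitions: int
    seed: int
    n_resampled: int = 0


def cross_validate(G: np.ndarray | GenotypePanel, y, folds: int = 5,
                   repetitions: int = 100, seed: int = 0) -> CvResult:
    """Repeated k-fold cross-validated predictive ability of RR-BLUP.

    Folds partition the genotypes anew in each repetition (seeded).
    Centering and the ridge parameter are re-estimated inside every
    training fold, so no information leaks from the validation set.
    Per-repetition ability is the mean over folds of the within-fold
    Pearson correlation; a pooled-over-folds correlation is also reported.
    """
    if isinstance(G, GenotypePanel):
        ids = G.ids
        G = G.dosage.astype(float)
        if isinstance(y, pd.Series):
            y = y.loc[ids].to_numpy(float)
    elif isinstance(y, pd.Series):
        y = y.to_numpy(float)
    y = np.asarray(y, float)
    G = np.asarray(G, float)
    n, m = G.shape
    if n < folds:
        raise ValueError("fewer genotypes than folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    P = G @ G.T                              # raw cross products, reused per fold

    assign = np.empty((repetitions, n), dtype=np.int64)
    fold_r = np.empty((repetitions, folds))
    pooled = np.empty(repetitions)
    n_resampled = 0
    for rep in range(repetitions):
        while True:
            perm = rng.permutation(n)
            fold_of = np.empty(n, dtype=np.int64)
            for f in range(folds):
                fold_of[perm[f::folds]] = f
            if np.bincount(fold_of, minlength=folds).min() >= 3:
                break
            n_resampled += 1
        assign[rep] = fold_of
        obs_all, pred_all = [], []
        for f in range(folds):
            te = np.flatnonzero(fold_of == f)
            tr = np.flatnonzero(fold_of != f)
            c = G[tr].mean(axis=0)
            a = G @ c                        # length n; per-fold centering terms
            cc = float(c @ c)
            Ktt = P[np.ix_(tr, tr)] - a[tr, None] - a[None, tr] + cc
            lamv, U = np.linalg.eigh(Ktt)
            lamv = np.maximum(lamv, 0.0)
            fit = eigen_reml(y[tr], np.ones((len(tr), 1)), lamv, U)
            mu = float(fit.beta[0])
            alpha = U @ ((U.T @ (y[tr] - mu)) / (lamv + fit.delta))
            Kvt = P[np.ix_(te, tr)] - a[te, None] - a[None, tr] + cc
            pred = mu + Kvt @ alpha
            r = np.corrcoef(y[te], pred)[0, 1]
            fold_r[rep, f] = r
            obs_all.append(y[te])
            pred_all.append(pred)
        pooled[rep] = np.corrcoef(np.concatenate(obs_all),
                                  np.concatenate(pred_all))[0, 1]
    per_rep = fold_r.mean(axis=1)
    return CvResult(fold_assignments=assign, per_fold_ability=fold_r,
                    per_repetition_ability=per_rep,
                    mean_ability=float(per_rep.mean()),
                    pooled_ability_per_rep=pooled, folds=folds,
                    repetitions=repetitions, seed=seed, n_resampled=n_resampled)
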