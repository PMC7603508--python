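"""Multi-locus mixed-model GWAS with kinship control.

The scan is a stepwise mixed-model regression: a polygenic background
``u ~ N(0, K s2_g)`` controls kinship and population structure, the
variance ratio is re-estimated once per step on a single spectral
decomposition of K, every non-cofactor SNP is tested as a fixed effect by
a generalized-least-squares Wald test in the rotated space, and the most
significant SNP is promoted to a fixed cofactor while it passes the
Bonferroni threshold alpha* = alpha / m. A backward pass drops cofactors
whose re-test p-value rises above alpha*. Significant SNPs are merged
into regions per chromosome within a fixed window, and the variance
explained by each significant SNP is the R^2 of a simple regression of
the phenotype on its dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypePanel
from .mixedlm import eigen_reml

log = logging.getLogger("refpop")


@dataclass
class KinshipMatrix:
    values: np.ndarray
    ids: list[str]
    freqs: np.ndarray            # centering allele frequencies per used marker
    n_excluded_monomorphic: int

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        w = np.linalg.eigvalsh(v)
        if w.min() < -1e-6 * max(w.max(), 1.0):
            raise ValueError("kinship matrix is not positive semidefinite")


def kinship(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    Dosages are centered by twice the allele frequency and the cross
    product is scaled by 2 * sum(p (1 - p)); monomorphic markers are
    excluded with a count.
    """
    D = panel.dosage.astype(float)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_excl = int((~poly).sum())
    if n_excl:
        log.info("kinship: excluded %d monomorphic markers", n_excl)
    M = D[:, poly] - 2 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1 - p[poly])))
    K = M @ M.T / denom
    return KinshipMatrix(values=K, ids=list(panel.ids), freqs=p[poly],
                         n_excluded_monomorphic=n_excl)


@dataclass
class GwasScan:
    tested_idx: np.ndarray               # panel marker indices after MAF filter
    pvalues: np.ndarray                  # per tested SNP, from its last test
    cofactors: list[int]                 # panel indices, order of entry
    alpha_star: float
    m: int
    significant_idx: np.ndarray          # panel indices with p < alpha*
    regions: pd.DataFrame                # chrom, start, end, best_snp, best_p, n_snps
    snp_r2: dict[int, float]             # per significant SNP
    steps: int = 0
    n_skipped_collinear: int = 0
    delta_per_step: list[float] = field(default_factory=list)


def mlmm_scan(panel: GenotypePanel, y: np.ndarray | pd.Series, K: KinshipMatrix,
              maf_min: float = 0.05, alpha: float = 0.05, max_steps: int = 10,
              merge_window_bp: float = 1e6) -> GwasScan:
    """Forward/backward multi-locus mixed-model scan with Bonferroni stopping."""
    if isinstance(y, pd.Series):
        y = y.loc[panel.ids].to_numpy(float)
    y = np.asarray(y, float)
    if len(y) != panel.n_individuals:
        raise ValueError("phenotype length does not match panel")

    maf = panel.maf()
    tested = np.flatnonzero(maf >= maf_min)
    m = len(tested)
    if m == 0:
        raise ValueError("no markers pass the MAF filter")
    alpha_star = alpha / m

    lam, U = np.linalg.eigh(K.values)
    lam = np.maximum(lam, 0.0)
    S = panel.dosage[:, tested].astype(float)
    UtS = U.T @ S

    pvals = np.full(m, np.nan)
    cofactors: list[int] = []          # positions within `tested`
    deltas: list[float] = []
    n_skipped = 0
    n = panel.n_individuals

    def design(cof):
        X = np.ones((n, 1 + len(cof)))
        for c, j in enumerate(cof):
            X[:, 1 + c] = S[:, j]
        return X

    step = 0
    while step < max_steps:
        step += 1
        fit = eigen_reml(y, design(cofactors), lam, U)
        deltas.append(fit.delta)
        cand = np.array([j for j in range(m) if j not in cofactors])
        _, _, p = fit.gls(UtS[:, cand])
        n_skipped += int(np.isnan(p).sum())
        pvals[cand] = p
        finite = np.nan_to_num(p, nan=1.0)
        best = int(cand[np.argmin(finite)])
        if finite.min() >= alpha_star:
            break
        cofactors.append(best)

    # backward pass: drop cofactors whose re-test p exceeds alpha*
    changed = True
    while changed and cofactors:
        changed = False
        for j in list(cofactors):
            others = [c for c in cofactors if c != j]
            f = eigen_reml(y, design(others), lam, U)
            _, _, p = f.gls(UtS[:, [j]])
            pvals[j] = p[0]
            if not np.isfinite(p[0]) or p[0] >= alpha_star:
                cofactors.remove(j)
                changed = True

    sig_local = np.flatnonzero(np.nan_to_num(pvals, nan=1.0) < alpha_star)
    sig_idx = tested[sig_local]
    regions = merge_regions(sig_idx, panel, merge_window_bp,
                            pvalues=pvals[sig_local])
    r2s = {int(i): snp_r2(panel.dosage[:, i], y) for i in sig_idx}
    return GwasScan(
        tested_idx=tested, pvalues=pvals, cofactors=[int(tested[c]) for c in cofactors],
        alpha_star=alpha_star, m=m, significant_idx=sig_idx, regions=regions,
        snp_r2=r2s, steps=step, n_skipped_collinear=n_skipped,
        delta_per_step=deltas,
    )


def merge_regions(significant_idx, panel: GenotypePanel,
                  merge_window_bp: float = 1e6,
                  pvalues: np.ndarray | None = None) -> pd.DataFrame:
    """Merge significant SNPs on one chromosome within a window into regions."""
    significant_idx = np.asarray(significant_idx, dtype=int)
    cols = ["chrom", "start", "end", "best_snp", "best_p", "n_snps"]
    if significant_idx.size == 0:
        return pd.DataFrame(columns=cols)
    keys = [GenotypePanel._chrom_key(c) for c in panel.chrom[significant_idx]]
    pos = panel.pos[significant_idx]
    order = sorted(range(len(significant_idx)), key=lambda t: (keys[t], pos[t]))
    idx = significant_idx[order]
    pv = pvalues[order] if pvalues is not None else np.ones(len(idx))
    rows = []
    cur = None
    for i, p in zip(idx, pv):
        c, pos = str(panel.chrom[i]), int(panel.pos[i])
        if cur is not None and cur["chrom"] == c and pos - cur["end"] <= merge_window_bp:
            cur["end"] = pos
            cur["n_snps"] += 1
            if p < cur["best_p"]:
                cur["best_p"], cur["best_snp"] = p, str(panel.marker_ids[i])
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": c, "start": pos, "end": pos,
                   "best_snp": str(panel.marker_ids[i]), "best_p": float(p),
                   "n_snps": 1}
    rows.append(cur)
    return pd.DataFrame(rows, columns=cols)


def snp_r2(dosage: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the simple regression of y on dosage."""
    x = np.asarray(dosage, float)
    y = np.asarray(y, float)
    if x.std() == 0:
        raise ValueError("snp_r2 undefined for a constant dosage vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
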