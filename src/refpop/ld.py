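"""Pairwise linkage disequilibrium, decay summaries, and sliding-window pruning.

LD is the squared Pearson correlation (r^2) between dosage vectors of two
markers on the same chromosome ("composite" genotype LD; no phase needed).
Decay is summarized by a locally weighted quadratic regression (tricube
weights, loess-style span) over distance, the distance at which the fitted
curve first drops below a threshold, and windowed mean r^2 at reference
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypePanel

DEFAULT_REF_DISTANCES = (100, 1_000, 5_000, 100_000)  # bp


def r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Raises ValueError for constant input (correlation undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("r2 needs two equal-length vectors of size >= 2")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("r2 undefined for a constant vector")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


@dataclass
class LdPairSample:
    """Sampled intra-chromosomal marker pairs with distances and r^2."""

    i: np.ndarray
    j: np.ndarray
    distance: np.ndarray
    r2: np.ndarray
    fraction: float
    seed: int
    n_excluded_constant: int = 0

    def __len__(self) -> int:
        return len(self.r2)


def sample_pairs(panel: GenotypePanel, fraction_per_chrom: float = 0.1,
                 max_pairs_for_smoother: int = 100_000, seed: int = 0
                 ) -> LdPairSample:
    """Score all intra-chromosomal pairs among a seeded per-chromosome sample.

    Within each chromosome, ceil(fraction * m_c) markers are drawn without
    replacement; every pair among them is scored. If the total exceeds
    ``max_pairs_for_smoother``, a seeded subsample of that size is kept.
    Constant markers give undefined r^2 and are excluded with a count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    ii, jj = [], []
    for c in panel.chromosomes():
        idx = np.flatnonzero(panel.chrom == c)
        k = int(np.ceil(fraction_per_chrom * len(idx)))
        chosen = np.sort(rng.choice(idx, size=k, replace=False))
        a, b = np.triu_indices(k, k=1)
        ii.extend(chosen[a].tolist())
        jj.extend(chosen[b].tolist())
    ii = np.asarray(ii, dtype=np.int64)
    jj = np.asarray(jj, dtype=np.int64)
    if len(ii) > max_pairs_for_smoother:
        keep = rng.choice(len(ii), size=max_pairs_for_smoother, replace=False)
        ii, jj = ii[keep], jj[keep]

    D = panel.dosage.astype(float)
    D = D - D.mean(axis=0)
    sd = D.std(axis=0)
    ok = (sd[ii] > 0) & (sd[jj] > 0)
    n_excl = int((~ok).sum())
    ii, jj = ii[ok], jj[ok]
    n = D.shape[0]
    corr = (D[:, ii] * D[:, jj]).sum(axis=0) / (n * sd[ii] * sd[jj])
    return LdPairSample(
        i=ii, j=jj, distance=np.abs(panel.pos[ii] - panel.pos[jj]).astype(float),
        r2=corr**2, fraction=fraction_per_chrom, seed=seed,
        n_excluded_constant=n_excl,
    )


@dataclass
class DecaySummary:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    threshold: float
    threshold_distance: float | None    # None when the curve never crosses
    windowed_means: dict[int, float | None]
    window_halfwidth_bp: float


def _local_quadratic(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float
                     ) -> np.ndarray:
    """Loess-style smoother: local quadratic fit with tricube weights.

    ``span`` is the fraction of points entering each local fit (nearest by
    distance). Exact equivalence to any particular loess implementation is
    not claimed.
    """
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    k = max(int(np.ceil(span * n)), 8)
    out = np.empty(len(grid))
    for gidx, g in enumerate(grid):
        d = np.abs(x - g)
        # nearest-k neighborhood via partial sort
        cut = np.partition(d, min(k, n) - 1)[min(k, n) - 1]
        sel = d <= cut
        xs, ys, ds = x[sel], y[sel], d[sel]
        h = max(cut, 1e-12)
        w = (1 - np.minimum(ds / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        t = (xs - g) / h          # scaled local coordinate for conditioning
        X = np.column_stack([np.ones_like(t), t, t**2])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * ys), rcond=None)
        out[gidx] = beta[0]
    return out


def decay_summary(pairs: LdPairSample, span: float = 0.5, threshold: float = 0.2,
                  ref_distances=DEFAULT_REF_DISTANCES, window_halfwidth_bp: float = 50.0,
                  n_grid: int = 200, threshold_within_bp: float = 5_000.0
                  ) -> DecaySummary:
    """Fit the decay smoother, locate the threshold crossing, window means.

    The genome-span smoother is evaluated on a log-spaced distance grid.
    The threshold distance follows the short-range convention: a second
    smoother is fitted to the pairs within ``threshold_within_bp`` only
    (the long-range bulk of near-zero r^2 would otherwise swamp the local
    fits), and the threshold distance is its first grid crossing below
    ``threshold``, linearly interpolated between grid points. Windowed
    means average all r^2 with distance within +/- ``window_halfwidth_bp``
    of each reference distance (undefined -> None).
    """
    if len(pairs) < 50:
        raise ValueError("decay_summary needs at least 50 pairs")
    d = np.maximum(pairs.distance, 1.0)
    grid = np.geomspace(d.min(), d.max(), n_grid)
    fitted = _local_quadratic(d, pairs.r2, grid, span)

    near = d <= threshold_within_bp
    thr_dist: float | None = None
    if near.sum() >= 50:
        ngrid = np.linspace(d[near].min(), d[near].max(), n_grid)
        nfit = _local_quadratic(d[near], pairs.r2[near], ngrid, span)
        below = nfit < threshold
        if below[0]:
            thr_dist = float(ngrid[0])
        else:
            for k in range(1, len(ngrid)):
                if below[k]:
                    x0, x1 = ngrid[k - 1], ngrid[k]
                    y0, y1 = nfit[k - 1], nfit[k]
                    thr_dist = float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))
                    break

    wmeans: dict[int, float | None] = {}
    for ref in ref_distances:
        sel = np.abs(pairs.distance - ref) <= window_halfwidth_bp
        wmeans[int(ref)] = float(pairs.r2[sel].mean()) if sel.any() else None
    return DecaySummary(grid=grid, fitted=fitted, span=span, threshold=threshold,
                        threshold_distance=thr_dist, windowed_means=wmeans,
                        window_halfwidth_bp=window_halfwidth_bp)


def ld_prune(panel: GenotypePanel, window: int = 50, step: int = 10,
             r2_max: float = 0.1) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained marker indices.

    Windows of ``window`` markers (map order, per chromosome) advance by
    ``step``; within a window, while any retained pair exceeds ``r2_max``
    the later marker of the offending pair is removed. Ties keep the
    earlier marker, so the result is deterministic.
    """
    D = panel.dosage.astype(float)
    D = D - D.mean(axis=0)
    sd = D.std(axis=0)
    n = D.shape[0]
    removed = np.zeros(panel.n_markers, dtype=bool)
    for c in panel.chromosomes():
        idx = np.flatnonzero(panel.chrom == c)
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            live = win[~removed[win] & (sd[win] > 0)]
            if len(live) > 1:
                B = D[:, live]
                R2 = (B.T @ B / (n * np.outer(sd[live], sd[live]))) ** 2
                keep_mask = np.ones(len(live), dtype=bool)
                for a in range(len(live)):
                    if not keep_mask[a]:
                        continue
                    offend = np.flatnonzero(keep_mask & (R2[a] > r2_max))
                    keep_mask[offend[offend > a]] = False
                removed[live[~keep_mask]] = True
            if start + window >= len(idx):
                break
    return np.flatnonzero(~removed)
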