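"""Family-based imputation from scaffold to full marker density, and its accuracy.

Full-scale localized-haplotype-cluster imputation is deliberately out of
scope; the imputer here is a transmission tracer for full-sib families
with phased parents. Per offspring and chromosome, a dynamic program over
the scaffold markers finds minimal-cost assignments of which parental
haplotype was transmitted by each parent (4 joint states), where each
genotype mismatch costs 1 and each haplotype switch (crossover) costs
``switch_penalty`` (default 2.0, so one crossover is cheaper than two
genotyping errors). Dense markers take the posterior over states that are
on at least one optimal path at the nearest scaffold anchor, with equal
weights under ties, giving a real-valued expected dosage in [0, 2].

Accuracy follows the validation convention of correlating imputed against
true dosages: "across individuals" is the mean over individuals of the
Pearson correlation over that individual's markers, "across markers" the
mean over markers of the correlation over individuals; zero-variance rows
or columns are excluded from the means and counted, not imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypePanel

STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (maternal hap, paternal hap)


@dataclass
class ImputationResult:
    imputed: np.ndarray                  # (n, m) expected dosage in [0, 2]
    per_individual_r: np.ndarray         # NaN where undefined
    per_marker_r: np.ndarray
    accuracy_individuals: float          # mean of defined per-individual r
    accuracy_markers: float
    fraction_imputed: float              # percent of values newly inferred
    n_undefined_individuals: int = 0
    n_undefined_markers: int = 0
    n_flagged_mendelian: int = 0
    ids: list[str] = field(default_factory=list)


def impute_family(mother: np.ndarray, father: np.ndarray,
                  offspring_scaffold: np.ndarray, chrom: np.ndarray,
                  scaffold_idx: np.ndarray, switch_penalty: float = 2.0,
                  round_calls: bool = False) -> tuple[np.ndarray, int]:
    """Impute one full-sib family to full density.

    Parameters
    ----------
    mother, father : (2, m_full) phased binary haplotypes.
    offspring_scaffold : (n_off, m_scaffold) dosages (MISSING allowed).
    chrom : (m_full,) chromosome label per full-map marker.
    scaffold_idx : positions of the scaffold markers within the full map.

    Returns the (n_off, m_full) expected dosage matrix and the count of
    Mendelian-inconsistent scaffold genotypes flagged and excluded.
    """
    m_full = mother.shape[1]
    n_off = offspring_scaffold.shape[0]
    out = np.empty((n_off, m_full))
    scaffold_idx = np.asarray(scaffold_idx, dtype=int)
    n_flagged = 0

    # per-state dosage at every full marker: d[s, j] = m_a[j] + f_b[j]
    state_dosage = np.stack([mother[a] + father[b] for a, b in STATES]).astype(np.int8)
    switch_cost = switch_penalty * np.array(
        [[(a1 != a2) + (b1 != b2) for (a2, b2) in STATES] for (a1, b1) in STATES],
        dtype=float,
    )

    chroms = pd.unique(chrom)
    for o in range(n_off):
        for c in chroms:
            full_j = np.flatnonzero(chrom == c)
            on_c = np.isin(scaffold_idx, full_j)
            sc_local = np.flatnonzero(on_c)             # scaffold-array positions
            sc_full = scaffold_idx[on_c]                # full-map positions
            obs = offspring_scaffold[o, sc_local]
            usable = obs != MISSING
            # Mendelian check: observed dosage must be reachable by some state
            reach = state_dosage[:, sc_full]
            ok = (reach == obs[None, :]).any(axis=0)
            flag = usable & ~ok
            n_flagged += int(flag.sum())
            usable &= ok
            anchors_full = sc_full[usable]
            emis = (reach[:, usable] != obs[usable][None, :]).astype(float)

            opt = _viterbi_optimal_states(emis, switch_cost)
            out[o, full_j] = _expected_dosage(full_j, anchors_full, opt,
                                              state_dosage)
            # scaffold pass-through for observed, consistent genotypes
            out[o, sc_full[usable]] = obs[usable]
    if round_calls:
        out = np.rint(out)
    return out, n_flagged


def _viterbi_optimal_states(emis: np.ndarray, switch_cost: np.ndarray
                            ) -> list[np.ndarray]:
    """States on at least one minimal-cost path, per anchor position."""
    k = emis.shape[1]
    if k == 0:
        return []
    F = np.zeros((k, 4))
    F[0] = emis[:, 0]
    for t in range(1, k):
        F[t] = emis[:, t] + (F[t - 1][:, None] + switch_cost).min(axis=0)
    B = np.zeros((k, 4))
    for t in range(k - 2, -1, -1):
        B[t] = (B[t + 1][None, :] + switch_cost + emis[:, t + 1][None, :]).min(axis=1)
    total = F[-1].min()
    return [np.flatnonzero(F[t] + B[t] <= total + 1e-9) for t in range(k)]


def _expected_dosage(full_j: np.ndarray, anchors_full: np.ndarray,
                     opt: list[np.ndarray], state_dosage: np.ndarray) -> np.ndarray:
    if len(anchors_full) == 0:
        return state_dosage[:, full_j].mean(axis=0)
    # nearest anchor (ties -> left) per dense marker
    pos = np.searchsorted(anchors_full, full_j)
    left = np.clip(pos - 1, 0, len(anchors_full) - 1)
    right = np.clip(pos, 0, len(anchors_full) - 1)
    d_left = np.abs(full_j - anchors_full[left])
    d_right = np.abs(anchors_full[right] - full_j)
    nearest = np.where(d_left <= d_right, left, right)
    vals = np.empty(len(full_j))
    for a in np.unique(nearest):
        states = opt[a]
        sel = nearest == a
        vals[sel] = state_dosage[np.ix_(states, full_j[sel])].mean(axis=0)
    return vals


def accuracy(imputed: np.ndarray, truth: np.ndarray,
             fraction: float = np.nan, ids: list[str] | None = None
             ) -> ImputationResult:
    """Pearson-correlation accuracy across individuals and across markers."""
    imputed = np.asarray(imputed, float)
    truth = np.asarray(truth, float)
    if imputed.shape != truth.shape:
        raise ValueError("imputed and truth matrices must have the same shape")
    per_ind = _rowwise_r(imputed, truth)
    per_mark = _rowwise_r(imputed.T, truth.T)
    return ImputationResult(
        imputed=imputed,
        per_individual_r=per_ind, per_marker_r=per_mark,
        accuracy_individuals=float(np.nanmean(per_ind)) if np.isfinite(per_ind).any() else np.nan,
        accuracy_markers=float(np.nanmean(per_mark)) if np.isfinite(per_mark).any() else np.nan,
        fraction_imputed=fraction,
        n_undefined_individuals=int(np.isnan(per_ind).sum()),
        n_undefined_markers=int(np.isnan(per_mark).sum()),
        ids=ids or [],
    )


def _rowwise_r(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac * Bc).sum(axis=1) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    return r


def fraction_imputed(scaffold_size: int, full_size: int) -> float:
    """Percent of marker values newly inferred: 100 (full - scaffold) / full."""
    if scaffold_size > full_size:
        raise ValueError("scaffold size cannot exceed full size")
    return 100.0 * (full_size - scaffold_size) / full_size


def evaluate_family_imputation(sim, switch_penalty: float = 2.0) -> ImputationResult:
    """Impute every simulated family from the scaffold panel and score it.

    ``sim`` is a :class:`refpop.simdata.SimResult`; parents' phased
    haplotypes come from the founder set, offspring scaffold genotypes from
    the masked panel, and the truth from the full-density panel.
    """
    panel = sim.panel
    scaffold = sim.scaffold
    hs = sim.haplotypes
    row = {g: i for i, g in enumerate(panel.ids)}
    imputed_rows, truth_rows, ids, flagged = [], [], [], 0
    for (mo, fa), kids in sim.pedigree.families().items():
        mh = hs.haplotypes[hs.ids.index(mo)]
        fh = hs.haplotypes[hs.ids.index(fa)]
        kid_rows = [row[k] for k in kids]
        off_sc = scaffold.dosage[kid_rows]
        imp, nf = impute_family(mh, fh, off_sc, panel.chrom, sim.scaffold_idx,
                                switch_penalty)
        flagged += nf
        imputed_rows.append(imp)
        truth_rows.append(panel.dosage[kid_rows])
        ids.extend(kids)
    res = accuracy(np.concatenate(imputed_rows), np.concatenate(truth_rows),
                   fraction=fraction_imputed(scaffold.n_markers, panel.n_markers),
                   ids=ids)
    res.n_flagged_mendelian = flagged
    return res
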