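"""SNP-density x feature-selection experiment.

Reruns the GWAS scan and cross-validated genomic prediction over marker
subsets chosen by three strategies — the scaffold (low-density array)
panel, an LD-thinned panel, and evenly spaced subsets at a ladder of
densities with several seeds — and summarizes region counts and
predictive abilities with normal-approximation 95% confidence intervals
over seeds. Kinship for the mixed-model scan is always computed from the
FULL panel, so density varies only the tested markers, and the Bonferroni
denominator adapts to the subset size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypePanel
from .gpred import cross_validate
from .gwas import KinshipMatrix, kinship, mlmm_scan
from . import ld as ldmod

log = logging.getLogger("refpop")

DEFAULT_DENSITIES = (500, 1_000, 5_000, 10_000, 50_000, 100_000,
                     150_000, 200_000, 250_000)


@dataclass
class DensityExperimentSpec:
    densities: tuple[int, ...] = DEFAULT_DENSITIES
    seeds_per_density: int = 10
    cv_repetitions: int = 10
    cv_folds: int = 5
    include_scaffold: bool = True
    include_ld_thinned: bool = True
    maf_min: float = 0.05
    alpha: float = 0.05
    max_steps: int = 10
    ld_prune_window: int = 50
    ld_prune_step: int = 10
    ld_prune_r2: float = 0.1

    def __post_init__(self) -> None:
        if self.seeds_per_density < 2:
            raise ValueError("need >= 2 seeds per density for a CI")


def evenly_spaced_subset(panel: GenotypePanel, m: int, seed: int = 0) -> np.ndarray:
    """Global map-order subset: indices congruent to a seeded random start.

    Stride is floor(M / m); the start is uniform on [0, stride); the
    subset is truncated from the end to exactly ``m`` markers.
    """
    M = panel.n_markers
    if m > M:
        raise ValueError("subset larger than panel")
    stride = M // m
    if stride <= 1:
        return np.arange(M)[:m] if m < M else np.arange(M)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 30]))
    start = int(rng.integers(0, stride))
    idx = np.arange(start, M, stride)
    return idx[:m]


@dataclass
class DensityGridResult:
    per_run: pd.DataFrame        # strategy, density, seed, n_regions, ability
    summary: pd.DataFrame        # strategy, density, means and 95% CIs


def run_grid(panel: GenotypePanel, y, spec: DensityExperimentSpec,
             K: KinshipMatrix | None = None, scaffold_idx: np.ndarray | None = None,
             seed: int = 0) -> DensityGridResult:
    """Run GWAS and prediction over all subsets of the experiment grid."""
    if K is None:
        K = kinship(panel)
    if isinstance(y, pd.Series):
        y = y.loc[panel.ids].to_numpy(float)
    y = np.asarray(y, float)

    densities = tuple(d for d in spec.densities if d <= panel.n_markers)
    runs: list[tuple[str, int, int, np.ndarray]] = []
    for d in densities:
        for s in range(spec.seeds_per_density):
            runs.append(("evenly_spaced", d, s,
                         evenly_spaced_subset(panel, d, seed=seed * 1000 + s)))
    if spec.include_scaffold and scaffold_idx is not None:
        runs.append(("scaffold_panel", len(scaffold_idx), 0,
                     np.asarray(scaffold_idx, int)))
    if spec.include_ld_thinned:
        pruned = ldmod.ld_prune(panel, spec.ld_prune_window, spec.ld_prune_step,
                                spec.ld_prune_r2)
        runs.append(("ld_thinned", len(pruned), 0, pruned))

    rows = []
    for strategy, d, s, idx in runs:
        if len(idx) < 100:
            log.warning("density %d below 100 markers; kinship stays full-panel", d)
        sub = panel.subset_markers(idx)
        scan = mlmm_scan(sub, y, K, maf_min=spec.maf_min, alpha=spec.alpha,
                         max_steps=spec.max_steps)
        cv = cross_validate(sub.dosage.astype(float), y, folds=spec.cv_folds,
                            repetitions=spec.cv_repetitions,
                            seed=seed * 1000 + 31 * s + d % 997)
        rows.append({"strategy": strategy, "density": d, "seed": s,
                     "n_regions": len(scan.regions), "ability": cv.mean_ability})
    per_run = pd.DataFrame(rows)

    summ = []
    for (strategy, d), grp in per_run.groupby(["strategy", "density"]):
        n = len(grp)
        rec = {"strategy": strategy, "density": d, "n_seeds": n,
               "mean_regions": grp["n_regions"].mean(),
               "mean_ability": grp["ability"].mean()}
        if strategy == "evenly_spaced" and n >= 2:
            for col, key in [("n_regions", "regions"), ("ability", "ability")]:
                se = grp[col].std(ddof=1) / np.sqrt(n)
                rec[f"{key}_ci_lo"] = grp[col].mean() - 1.96 * se
                rec[f"{key}_ci_hi"] = grp[col].mean() + 1.96 * se
        summ.append(rec)
    return DensityGridResult(per_run=per_run, summary=pd.DataFrame(summ))
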