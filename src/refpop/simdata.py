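"""Synthetic REFPOP-like populations with known ground truth.

The generator emulates the structure of a pedigreed apple reference
population: a founder ("accession") group drawn from origin groups with weak
allele-frequency clines, full-sib progeny families produced by simulated
meiosis, a dense biallelic SNP panel on 17 chromosomes with rapid LD decay,
a nested low-density scaffold panel, and tree-level day-of-year phenotypes
over multi-environment complete-block field trials with planted spatial
surfaces, environment effects, G x E, and residual noise.

Founder haplotypes follow a first-order copy/mutate Markov process along
each chromosome: the allele at a marker copies the previous marker's allele
with probability exp(-d / ld_decay_bp) (d = inter-marker distance in bp) and
is otherwise drawn fresh from the marker's allele frequency. This gives an
approximately exponential decay of haplotype allele correlation with
distance, which is the only LD feature downstream stages depend on.
Meiosis uses a Poisson crossover count per chromosome with uniform crossover
positions and no interference (Haldane model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import GenotypePanel, Pedigree, PedigreeRecord, TreeRecordTable
import pandas as pd

DEFAULT_ORIGINS = {
    "NEE": 28, "WCE": 134, "SE": 22, "SEE": 10,
    "ANZ": 8, "CAN": 16, "JPN": 9, "USA": 34, "ZAF": 2, "U": 6,
}


@dataclass
class TraitSpec:
    """Architecture and variance decomposition of one simulated trait.

    Variance fractions are proportions of the total phenotypic variance
    attributable to genotype, environment, G x E, the spatial field surface,
    and residual noise; they must sum to 1. ``trait_offset_days`` is the
    day-of-year baseline and ``total_sd_days`` the overall phenotypic SD.
    """

    name: str
    n_causal: int = 100
    var_fraction_genotype: float = 0.74
    var_fraction_environment: float = 0.05
    var_fraction_gxe: float = 0.12
    var_fraction_spatial: float = 0.04
    var_fraction_residual: float = 0.05
    trait_offset_days: float = 250.0
    total_sd_days: float = 10.0

    def fractions(self) -> dict[str, float]:
        return {
            "genotype": self.var_fraction_genotype,
            "environment": self.var_fraction_environment,
            "gxe": self.var_fraction_gxe,
            "spatial": self.var_fraction_spatial,
            "residual": self.var_fraction_residual,
        }

    def __post_init__(self) -> None:
        fr = self.fractions()
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {sum(fr.values())}, not 1")
        if self.n_causal < 1:
            raise ValueError("n_causal must be positive")


@dataclass
class SimConfig:
    """Desk-scale population design mirroring the reference-population layout."""

    n_accessions: int = 269
    origin_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ORIGINS))
    n_families: int = 27
    progeny_per_family: int = 10
    n_chromosomes: int = 17
    chrom_length_bp: int = 2_400_000
    n_snps_full: int = 20_000
    n_snps_scaffold: int = 1_000
    ld_decay_bp: float = 3_000.0
    maf_min: float = 0.05
    origin_freq_sd: float = 0.03
    recomb_rate: float = 1.5  # expected crossovers per chromosome per meiosis
    trait_specs: list[TraitSpec] = field(default_factory=lambda: [TraitSpec("harvest")])
    n_environments: int = 6
    blocks_per_environment: int = 2
    field_rows: int | None = None
    field_cols: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.origin_counts.values()) != self.n_accessions:
            raise ValueError("origin_counts must sum to n_accessions")
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.n_snps_scaffold > self.n_snps_full:
            raise ValueError("scaffold panel cannot exceed full panel")
        for name, v in [
            ("n_accessions", self.n_accessions), ("n_families", self.n_families),
            ("progeny_per_family", self.progeny_per_family),
            ("n_chromosomes", self.n_chromosomes), ("n_snps_full", self.n_snps_full),
            ("n_environments", self.n_environments),
            ("blocks_per_environment", self.blocks_per_environment),
        ]:
            if v < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (n, 2, m) over a shared marker map."""

    ids: list[str]
    haplotypes: np.ndarray  # (n, 2, m) uint8
    chrom: np.ndarray
    pos: np.ndarray
    marker_ids: np.ndarray
    founder: np.ndarray  # (n,) bool

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(np.int16)

    def to_panel(self, group: dict | None = None) -> GenotypePanel:
        return GenotypePanel(
            ids=list(self.ids), dosage=self.dosage(),
            chrom=self.chrom, pos=self.pos, marker_ids=self.marker_ids,
            group=group or {},
        )

    def entry(self, id_: str) -> np.ndarray:
        return self.haplotypes[self.ids.index(id_)]


@dataclass
class TruthSet:
    """Ground truth stored for parameter-recovery tests."""

    trait: str
    causal_idx: np.ndarray
    effects: np.ndarray
    tbv: dict[str, float]               # scaled true breeding value per genotype
    env_effects: dict[str, float]
    gxe: dict[tuple[str, str], float]
    spatial: dict[str, np.ndarray]      # per-environment (rows, cols) surface
    realized_fractions: dict[str, float]


# ------------------------------------------------------------------ founders

def _marker_map(cfg: SimConfig, rng: np.random.Generator):
    per = np.full(cfg.n_chromosomes, cfg.n_snps_full // cfg.n_chromosomes)
    per[: cfg.n_snps_full % cfg.n_chromosomes] += 1
    chrom, pos, ids = [], [], []
    for c in range(cfg.n_chromosomes):
        p = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1), size=per[c], replace=False))
        chrom.extend([str(c + 1)] * per[c])
        pos.extend(p.tolist())
        ids.extend(f"snp_{c + 1}_{x}" for x in p)
    return (np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
            np.array(ids, dtype=object))


def _markov_haplotypes(n_hap, chrom, pos, freqs, ld_decay_bp, rng):
    """First-order copy process along each chromosome, vectorized over haplotypes."""
    m = len(pos)
    H = np.empty((n_hap, m), dtype=np.uint8)
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        d = np.diff(pos[idx]).astype(float)
        copy_p = np.exp(-d / ld_decay_bp) if ld_decay_bp > 0 else np.zeros_like(d)
        block = np.empty((n_hap, len(idx)), dtype=np.uint8)
        block[:, 0] = rng.random(n_hap) < freqs[:, idx[0]]
        for k in range(1, len(idx)):
            fresh = rng.random(n_hap) < freqs[:, idx[k]]
            copy = rng.random(n_hap) < copy_p[k - 1]
            block[:, k] = np.where(copy, block[:, k - 1], fresh)
        H[:, idx] = block
        start += len(idx)
    return H


def simulate_founders(cfg: SimConfig, max_resample_rounds: int = 30
                      ) -> tuple[HaplotypeSet, GenotypePanel]:
    """Simulate the founder (accession) group.

    Returns phased haplotypes and the corresponding dosage panel with origin
    labels. Markers whose realized MAF falls below ``cfg.maf_min`` are
    resampled (fresh independent draws at those markers only) for a bounded
    number of rounds; if markers still fail, the constraint is infeasible
    and a ValueError is raised.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos, mids = _marker_map(cfg, rng)
    m = len(pos)
    base = rng.uniform(max(0.1, cfg.maf_min), 1 - max(0.1, cfg.maf_min), size=m)

    origins, counts = zip(*cfg.origin_counts.items())
    shifts = {o: rng.normal(0.0, cfg.origin_freq_sd, size=m) for o in origins}
    origin_per_ind = np.repeat(origins, counts)
    freq_per_hap = np.empty((2 * cfg.n_accessions, m))
    for i, o in enumerate(origin_per_ind):
        f = np.clip(base + shifts[o], 0.01, 0.99)
        freq_per_hap[2 * i] = f
        freq_per_hap[2 * i + 1] = f

    H = _markov_haplotypes(2 * cfg.n_accessions, chrom, pos, freq_per_hap,
                           cfg.ld_decay_bp, rng)
    bad = np.array([], dtype=int)
    for round_ in range(max_resample_rounds + 1):
        p = H.mean(axis=0)
        bad = np.flatnonzero(np.minimum(p, 1 - p) < cfg.maf_min)
        if bad.size == 0:
            break
        if round_ == max_resample_rounds:
            raise ValueError(
                f"MAF >= {cfg.maf_min} infeasible: {bad.size} markers still "
                "below floor after resampling"
            )
        H[:, bad] = rng.random((H.shape[0], bad.size)) < base[bad]

    ids = [f"acc_{i:03d}" for i in range(cfg.n_accessions)]
    haps = H.reshape(cfg.n_accessions, 2, m)
    hs = HaplotypeSet(ids=ids, haplotypes=haps, chrom=chrom, pos=pos,
                      marker_ids=mids, founder=np.ones(cfg.n_accessions, bool))
    panel = hs.to_panel(group={"type": ["accession"] * cfg.n_accessions,
                               "origin": list(origin_per_ind)})
    return hs, panel


# ------------------------------------------------------------------- crosses

def _gamete(parent_haps: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
            recomb_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete: Poisson crossovers, uniform positions, per chromosome."""
    m = parent_haps.shape[1]
    gam = np.empty(m, dtype=np.uint8)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        lo, hi = pos[idx[0]], pos[idx[-1]]
        n_x = rng.poisson(recomb_rate)
        breaks = np.sort(rng.uniform(lo, hi, size=n_x))
        phase = rng.integers(0, 2)
        seg = phase + np.searchsorted(breaks, pos[idx], side="right")
        gam[idx] = np.where(seg % 2 == 0, parent_haps[0, idx], parent_haps[1, idx])
    return gam


def simulate_cross(mother: np.ndarray, father: np.ndarray, n_offspring: int,
                   chrom: np.ndarray, pos: np.ndarray, recomb_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Full-sib family: (n_offspring, 2, m) haplotypes; slot 0 maternal, 1 paternal."""
    m = mother.shape[1]
    out = np.empty((n_offspring, 2, m), dtype=np.uint8)
    for k in range(n_offspring):
        out[k, 0] = _gamete(mother, chrom, pos, recomb_rate, rng)
        out[k, 1] = _gamete(father, chrom, pos, recomb_rate, rng)
    return out


def simulate_progeny(cfg: SimConfig, founders: HaplotypeSet
                     ) -> tuple[HaplotypeSet, Pedigree]:
    """Draw parental combinations and simulate all full-sib families."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    pairs: list[tuple[str, str]] = []
    while len(pairs) < cfg.n_families:
        i, j = rng.choice(len(founders.ids), size=2, replace=False)
        pair = (founders.ids[i], founders.ids[j])
        if pair not in pairs:
            pairs.append(pair)
    ids, haps, records = [], [], []
    records = [PedigreeRecord(i, None, None) for i in founders.ids]
    for f, (mo, fa) in enumerate(pairs):
        fam = simulate_cross(founders.entry(mo), founders.entry(fa),
                             cfg.progeny_per_family, founders.chrom, founders.pos,
                             cfg.recomb_rate, rng)
        for k in range(cfg.progeny_per_family):
            pid = f"prog_{f:02d}_{k:02d}"
            ids.append(pid)
            records.append(PedigreeRecord(pid, mo, fa))
        haps.append(fam)
    hs = HaplotypeSet(
        ids=ids, haplotypes=np.concatenate(haps, axis=0),
        chrom=founders.chrom, pos=founders.pos, marker_ids=founders.marker_ids,
        founder=np.zeros(len(ids), bool),
    )
    return hs, Pedigree(records)


def combine(founders: HaplotypeSet, progeny: HaplotypeSet) -> HaplotypeSet:
    return HaplotypeSet(
        ids=list(founders.ids) + list(progeny.ids),
        haplotypes=np.concatenate([founders.haplotypes, progeny.haplotypes]),
        chrom=founders.chrom, pos=founders.pos, marker_ids=founders.marker_ids,
        founder=np.concatenate([founders.founder, progeny.founder]),
    )


# ---------------------------------------------------------------- phenotypes

def _scale_to(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale to an exact sample variance (zeros if degenerate)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    sd = x.std()
    if target_var <= 0 or sd == 0:
        return np.zeros_like(x)
    return x * (np.sqrt(target_var) / sd)


def _spatial_surface(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of 3 Gaussian bumps plus a linear trend (unscaled)."""
    u, v = np.meshgrid(np.arange(rows, dtype=float), np.arange(cols, dtype=float),
                       indexing="ij")
    s = rng.normal(0, 0.3) * u / max(rows - 1, 1) + rng.normal(0, 0.3) * v / max(cols - 1, 1)
    for _ in range(3):
        cu, cv = rng.uniform(0, rows), rng.uniform(0, cols)
        w = rng.uniform(0.15, 0.45) * max(rows, cols)
        s += rng.normal(0, 1.0) * np.exp(-(((u - cu) ** 2 + (v - cv) ** 2) / (2 * w**2)))
    return s


def field_layout(n_genotypes: int, blocks: int, field_rows: int | None,
                 field_cols: int | None):
    """Rows/cols large enough to hold ``blocks`` complete blocks, stacked by row."""
    per_block_cols = field_cols or int(np.ceil(np.sqrt(n_genotypes)))
    per_block_rows = int(np.ceil(n_genotypes / per_block_cols))
    rows = field_rows or per_block_rows * blocks
    if rows * per_block_cols < n_genotypes * blocks:
        raise ValueError("field layout too small for complete blocks")
    return rows, per_block_cols, per_block_rows


def simulate_phenotypes(panel: GenotypePanel, spec: TraitSpec, *,
                        n_environments: int = 6, blocks: int = 2,
                        field_rows: int | None = None, field_cols: int | None = None,
                        seed: int = 0, round_days: bool = False
                        ) -> tuple[TreeRecordTable, TruthSet]:
    """Tree-level phenotypes on a complete-block multi-environment design.

    Each tree value = offset + TBV + environment effect + G x E deviation +
    spatial surface value at its (row, col) + residual, with every component
    centered and scaled so the realized variance fractions over trees equal
    the TraitSpec exactly (cross-terms aside). Day-of-year values are real-valued
    unless ``round_days``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = panel.n_individuals
    rows, cols, per_block_rows = field_layout(n, blocks, field_rows, field_cols)
    envs = [f"ENV{j + 1}" for j in range(n_environments)]

    # genetic values from causal loci
    causal = np.sort(rng.choice(panel.n_markers, size=spec.n_causal, replace=False))
    effects = rng.normal(0, 1, size=spec.n_causal)
    raw_tbv = panel.dosage[:, causal].astype(float) @ effects

    # assemble the tree table (genotype placement seeded per env/block)
    recs = []
    for j, env in enumerate(envs):
        for b in range(blocks):
            perm = rng.permutation(n)
            for slot, gi in enumerate(perm):
                r = b * per_block_rows + slot // cols
                c = slot % cols
                recs.append((panel.ids[gi], env, b + 1, r, c, gi, j))
    df = pd.DataFrame(recs, columns=["genotype", "environment", "block",
                                     "row", "col", "_gi", "_ej"])
    n_trees = len(df)
    var = {k: f * spec.total_sd_days**2 for k, f in spec.fractions().items()}

    g_term = _scale_to(raw_tbv[df["_gi"]], var["genotype"])
    env_raw = rng.normal(0, 1, size=n_environments)
    e_term = _scale_to(env_raw[df["_ej"]], var["environment"])
    gxe_raw = rng.normal(0, 1, size=(n, n_environments))
    # double-center so G x E is exactly orthogonal to genotype and environment
    gxe_raw -= gxe_raw.mean(axis=1, keepdims=True)
    gxe_raw -= gxe_raw.mean(axis=0, keepdims=True)
    x_term = _scale_to(gxe_raw[df["_gi"], df["_ej"]], var["gxe"])
    surfaces = {env: _spatial_surface(rows, cols, rng) for env in envs}
    s_raw = np.array([surfaces[env][r, c]
                      for env, r, c in zip(df["environment"], df["row"], df["col"])])
    # center within environment so the surface does not leak into env effects
    s_env_mean = pd.Series(s_raw).groupby(df["environment"].values).transform("mean")
    s_raw = s_raw - s_env_mean.to_numpy()
    s_term = _scale_to(s_raw, var["spatial"])
    r_term = _scale_to(rng.normal(0, 1, size=n_trees), var["residual"])

    value = spec.trait_offset_days + g_term + e_term + x_term + s_term + r_term
    if round_days:
        value = np.rint(value)
    df["trait"] = spec.name
    df["value"] = value

    total = value.var()
    realized = {
        "genotype": g_term.var() / total, "environment": e_term.var() / total,
        "gxe": x_term.var() / total, "spatial": s_term.var() / total,
        "residual": r_term.var() / total,
    }
    # store components on the scale actually used
    tbv_by_geno = {panel.ids[gi]: float(t) for gi, t in zip(df["_gi"], g_term)}
    env_by_env = {env: float(t) for env, t in zip(df["environment"], e_term)}
    gxe_by_cell = {(panel.ids[gi], env): float(t)
                   for gi, env, t in zip(df["_gi"], df["environment"], x_term)}

    truth = TruthSet(
        trait=spec.name, causal_idx=causal, effects=effects,
        tbv=tbv_by_geno, env_effects=env_by_env, gxe=gxe_by_cell,
        spatial={env: surfaces[env] * (s_term.std() / s_raw.std() if s_raw.std() > 0 else 0.0)
                 for env in envs},
        realized_fractions=realized,
    )
    table = TreeRecordTable(df.drop(columns=["_gi", "_ej"]))
    return table, truth


# ------------------------------------------------------------------ scaffold

def mask_to_scaffold(panel: GenotypePanel, n_snps_scaffold: int, seed: int = 0
                     ) -> tuple[GenotypePanel, np.ndarray]:
    """Evenly spread (map-order) scaffold subset; returns panel + full-map indices.

    Per-chromosome allocations are proportional to marker counts (largest
    remainder), positions within a chromosome evenly spaced from a seeded
    random start, so the subset is deterministic given the seed.
    """
    if n_snps_scaffold > panel.n_markers:
        raise ValueError("scaffold size exceeds panel size")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    chroms = panel.chromosomes()
    counts = np.array([(panel.chrom == c).sum() for c in chroms])
    exact = n_snps_scaffold * counts / counts.sum()
    alloc = np.floor(exact).astype(int)
    rem = np.argsort(-(exact - alloc))
    for i in rem[: n_snps_scaffold - alloc.sum()]:
        alloc[i] += 1
    keep = []
    for c, k in zip(chroms, alloc):
        idx = np.flatnonzero(panel.chrom == c)
        if k == 0:
            continue
        stride = len(idx) / k
        start = rng.uniform(0, stride)
        sel = np.unique((start + stride * np.arange(k)).astype(int))
        sel = sel[sel < len(idx)]
        keep.extend(idx[sel].tolist())
    keep = np.array(sorted(keep))
    sub = panel.subset_markers(keep)
    sub.tier = "scaffold"
    return sub, keep


# ----------------------------------------------------------------- top level

@dataclass
class SimResult:
    config: SimConfig
    haplotypes: HaplotypeSet          # founders + progeny, phased
    panel: GenotypePanel              # full-density dosage panel
    scaffold: GenotypePanel
    scaffold_idx: np.ndarray
    pedigree: Pedigree
    phenotypes: TreeRecordTable
    truth: dict[str, TruthSet]


def simulate_population(cfg: SimConfig) -> SimResult:
    """Run the full generator: founders, families, scaffold, phenotypes."""
    founders, fpanel = simulate_founders(cfg)
    progeny, pedigree = simulate_progeny(cfg, founders)
    allh = combine(founders, progeny)
    group = {
        "type": ["accession"] * len(founders.ids) + ["progeny"] * len(progeny.ids),
        "origin": list(fpanel.group["origin"]) + ["P"] * len(progeny.ids),
    }
    panel = allh.to_panel(group=group)
    scaffold, keep = mask_to_scaffold(panel, cfg.n_snps_scaffold, seed=cfg.seed)
    tables, truth = [], {}
    for spec in cfg.trait_specs:
        t, tr = simulate_phenotypes(
            panel, spec, n_environments=cfg.n_environments,
            blocks=cfg.blocks_per_environment, field_rows=cfg.field_rows,
            field_cols=cfg.field_cols, seed=cfg.seed,
        )
        tables.append(t.df)
        truth[spec.name] = tr
    phenos = TreeRecordTable(pd.concat(tables, ignore_index=True))
    return SimResult(cfg, allh, panel, scaffold, keep, pedigree, phenos, truth)
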