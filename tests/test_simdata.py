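"""Generator contracts: LD limits, meiosis, Mendelian consistency,
variance-fraction realization, scaffold masking, determinism."""

import numpy as np
import pytest

from refpop import ld, simdata
from refpop.datamodel import MISSING


def _cfg(**kw):
    base = dict(n_accessions=60, origin_counts={"A": 30, "B": 30}, n_families=3,
                progeny_per_family=4, n_chromosomes=2, n_snps_full=400,
                n_snps_scaffold=40, chrom_length_bp=400_000, seed=7,
                n_environments=2)
    base.update(kw)
    return simdata.SimConfig(**base)


class TestConfigValidation:
    def test_origin_counts_must_sum(self):
        with pytest.raises(ValueError, match="origin_counts"):
            simdata.SimConfig(n_accessions=10, origin_counts={"A": 5})

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            simdata.TraitSpec("t", var_fraction_genotype=0.9,
                              var_fraction_environment=0.9,
                              var_fraction_gxe=0, var_fraction_spatial=0,
                              var_fraction_residual=0)

    def test_maf_bounds(self):
        with pytest.raises(ValueError, match="maf_min"):
            _cfg(maf_min=0.6)


class TestFounders:
    def test_maf_floor_holds(self, small_sim):
        assert small_sim.panel.maf().min() >= small_sim.config.maf_min - 1e-12

    def test_independence_limit(self):
        """ld_decay -> 0 removes linkage: mean r^2 at ~1 kb is near zero."""
        hs, panel = simdata.simulate_founders(_cfg(ld_decay_bp=1e-9, seed=2))
        pairs = ld.sample_pairs(panel, fraction_per_chrom=0.4, seed=2)
        near = pairs.r2[(pairs.distance > 0) & (pairs.distance < 5000)]
        assert near.mean() < 0.05

    def test_full_linkage_limit(self):
        """ld_decay -> infinity: adjacent markers are copies, r^2 ~ 1."""
        hs, panel = simdata.simulate_founders(_cfg(ld_decay_bp=1e12, seed=2))
        r2s = []
        for c in panel.chromosomes():
            idx = np.flatnonzero(panel.chrom == c)
            for a, b in zip(idx[:-1], idx[1:]):
                r2s.append(ld.r2(panel.dosage[:, a], panel.dosage[:, b]))
        assert np.mean(r2s) > 0.99

    def test_origin_labels_assigned(self, small_sim):
        origins = small_sim.panel.group["origin"]
        assert origins.count("A") == 30 and origins.count("B") == 30

    def test_infeasible_maf_raises(self):
        """With no resampling budget, a tight MAF floor cannot be met."""
        with pytest.raises(ValueError, match="infeasible"):
            simdata.simulate_founders(_cfg(maf_min=0.45, seed=0),
                                      max_resample_rounds=0)


class TestCrosses:
    def test_no_crossover_transmits_intact_haplotypes(self):
        cfg = _cfg(recomb_rate=0.0)
        founders, _ = simdata.simulate_founders(cfg)
        rng = np.random.default_rng(0)
        fam = simdata.simulate_cross(founders.haplotypes[0], founders.haplotypes[1],
                                     20, founders.chrom, founders.pos, 0.0, rng)
        for k in range(20):
            for c in np.unique(founders.chrom):
                idx = founders.chrom == c
                mat = fam[k, 0, idx]
                assert (np.array_equal(mat, founders.haplotypes[0, 0, idx])
                        or np.array_equal(mat, founders.haplotypes[0, 1, idx]))

    def test_selfing_homozygous_parent_clones_it(self):
        cfg = _cfg()
        founders, _ = simdata.simulate_founders(cfg)
        hom = founders.haplotypes[0].copy()
        hom[1] = hom[0]
        rng = np.random.default_rng(1)
        fam = simdata.simulate_cross(hom, hom, 5, founders.chrom, founders.pos,
                                     1.5, rng)
        assert np.array_equal(fam.sum(axis=1), np.tile(2 * hom[0], (5, 1)))

    def test_crossover_count_mean(self):
        """200 gametes at rate 1.5: observed breakpoints within 3 SE of 1.5."""
        cfg = _cfg(n_snps_full=2000, chrom_length_bp=2_000_000, seed=7)
        founders, _ = simdata.simulate_founders(cfg)
        # heterozygous-everywhere synthetic parent so every crossover is visible
        par = np.zeros_like(founders.haplotypes[0])
        par[1] = 1
        rng = np.random.default_rng(7)
        fam = simdata.simulate_cross(par, par, 200, founders.chrom, founders.pos,
                                     1.5, rng)
        counts = []
        for k in range(200):
            for c in np.unique(founders.chrom):
                g = fam[k, 0, founders.chrom == c]
                counts.append(int(np.sum(np.abs(np.diff(g.astype(int))))))
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 1.5) < 3 * se + 0.05

    def test_mendelian_consistency_all_trios(self, small_sim):
        """No offspring/parent opposing-homozygote conflicts, exhaustively."""
        panel = small_sim.panel
        row = {g: i for i, g in enumerate(panel.ids)}
        for rec in small_sim.pedigree.records:
            if rec.mother is None:
                continue
            o = panel.dosage[row[rec.id]]
            for parent in (rec.mother, rec.father):
                p = panel.dosage[row[parent]]
                assert not np.any((o == 0) & (p == 2))
                assert not np.any((o == 2) & (p == 0))


class TestPhenotypes:
    def test_pure_noise_limit(self):
        cfg = _cfg()
        founders, panel = simdata.simulate_founders(cfg)
        spec = simdata.TraitSpec("noise", var_fraction_genotype=0,
                                 var_fraction_environment=0, var_fraction_gxe=0,
                                 var_fraction_spatial=0, var_fraction_residual=1)
        table, truth = simdata.simulate_phenotypes(panel, spec, n_environments=2,
                                                   seed=5)
        from refpop import pheno
        h = pheno.h2_individual(table, "ENV1", "noise")
        assert h.H2 < 0.15

    def test_pure_genotype_limit(self):
        cfg = _cfg()
        _, panel = simdata.simulate_founders(cfg)
        spec = simdata.TraitSpec("g", var_fraction_genotype=1,
                                 var_fraction_environment=0, var_fraction_gxe=0,
                                 var_fraction_spatial=0, var_fraction_residual=0)
        table, _ = simdata.simulate_phenotypes(panel, spec, n_environments=1, seed=5)
        reps = table.df.groupby("genotype")["value"].nunique()
        assert (reps == 1).all()
        from refpop import pheno
        assert pheno.h2_individual(table, "ENV1", "g").H2 > 1 - 1e-6

    def test_realized_fractions_match_spec(self, study_sim):
        realized = study_sim.truth["harvest"].realized_fractions
        spec = study_sim.config.trait_specs[0].fractions()
        for k, v in spec.items():
            assert abs(realized[k] - v) < 0.02, k

    def test_tbv_derives_from_causal_loci(self, small_sim):
        truth = small_sim.truth["harvest"]
        panel = small_sim.panel
        raw = panel.dosage[:, truth.causal_idx].astype(float) @ truth.effects
        stored = np.array([truth.tbv[g] for g in panel.ids])
        # stored TBV is an affine rescaling of the raw causal sum
        r = np.corrcoef(raw, stored)[0, 1]
        assert r > 0.999999


class TestScaffold:
    def test_identity_masking(self, small_sim):
        panel = small_sim.panel
        sub, idx = simdata.mask_to_scaffold(panel, panel.n_markers, seed=0)
        assert np.array_equal(idx, np.arange(panel.n_markers))
        assert np.array_equal(sub.dosage, panel.dosage)

    def test_per_chromosome_proportionality(self, desk_sim):
        panel = desk_sim.panel
        sub, idx = simdata.mask_to_scaffold(panel, 1000, seed=3)
        assert len(idx) == 1000
        for c in panel.chromosomes():
            m_c = (panel.chrom == c).sum()
            share = 1000 * m_c / panel.n_markers
            got = (sub.chrom == c).sum()
            assert abs(got - share) <= 1

    def test_missing_fraction_after_reexpansion(self, desk_sim):
        from refpop.imputeval import fraction_imputed
        panel = desk_sim.panel
        sub, idx = simdata.mask_to_scaffold(panel, 1000, seed=3)
        full = np.full(panel.dosage.shape, MISSING, dtype=np.int16)
        full[:, idx] = sub.dosage
        assert (full == MISSING).mean() == pytest.approx(0.95)
        assert fraction_imputed(1000, 20000) == pytest.approx(95.0)

    def test_roundtrip_indices(self, small_sim):
        panel = small_sim.panel
        sub, idx = simdata.mask_to_scaffold(panel, 50, seed=1)
        assert np.array_equal(panel.dosage[:, idx], sub.dosage)
        assert np.array_equal(panel.marker_ids[idx], sub.marker_ids)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = _cfg(seed=42)
        a = simdata.simulate_population(cfg)
        b = simdata.simulate_population(_cfg(seed=42))
        assert np.array_equal(a.panel.dosage, b.panel.dosage)
        assert np.array_equal(a.haplotypes.haplotypes, b.haplotypes.haplotypes)
        assert a.phenotypes.df.equals(b.phenotypes.df)
        assert np.array_equal(a.scaffold_idx, b.scaffold_idx)

    def test_different_seed_differs(self):
        a = simdata.simulate_population(_cfg(seed=1))
        b = simdata.simulate_population(_cfg(seed=2))
        assert not np.array_equal(a.panel.dosage, b.panel.dosage)
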