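"""LD statistics: r^2 values, pair sampling counts, decay smoother, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refpop import ld, simdata
from refpop.datamodel import GenotypePanel


def _panel(dosage, pos=None, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 100
    chrom = np.asarray(chrom, dtype=object) if chrom is not None \
        else np.array(["1"] * m, dtype=object)
    return GenotypePanel(ids=[f"i{k}" for k in range(n)], dosage=dosage,
                         chrom=chrom, pos=pos,
                         marker_ids=np.array([f"m{k}" for k in range(m)], dtype=object))


class TestR2:
    @pytest.mark.parametrize("x,y,expected", [
        ([0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2], 1.0),
        ([0, 0, 2, 2], [0, 2, 0, 2], 0.0),
        ([0, 1, 2, 2], [0, 1, 1, 2], 8 / 11),   # hand Pearson: r^2 = 4/5.5
    ])
    def test_values(self, x, y, expected):
        assert ld.r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ld.r2([1, 1, 1], [0, 1, 2])

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=12),
           st.lists(st.integers(0, 2), min_size=4, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, xs, ys):
        k = min(len(xs), len(ys))
        x, y = np.array(xs[:k]), np.array(ys[:k])
        if x.std() == 0 or y.std() == 0:
            return
        assert ld.r2(x, y) == pytest.approx(ld.r2(y, x), abs=1e-12)


class TestSamplePairs:
    def test_ten_markers_yield_no_pairs(self, rng):
        panel = _panel(rng.integers(0, 3, (20, 10)))
        pairs = ld.sample_pairs(panel, fraction_per_chrom=0.1, seed=0)
        assert len(pairs) == 0

    def test_hundred_markers_yield_45_pairs(self, rng):
        panel = _panel(rng.integers(0, 3, (20, 100)))
        pairs = ld.sample_pairs(panel, fraction_per_chrom=0.1, seed=0)
        assert len(pairs) + pairs.n_excluded_constant == 45

    def test_multi_chromosome_count(self, rng):
        m_per, n_chrom = 60, 4
        dosage = rng.integers(0, 3, (30, m_per * n_chrom))
        chrom = np.repeat([str(c + 1) for c in range(n_chrom)], m_per)
        pos = np.tile(np.arange(1, m_per + 1) * 10, n_chrom)
        panel = _panel(dosage, pos=pos, chrom=chrom)
        pairs = ld.sample_pairs(panel, fraction_per_chrom=0.1, seed=1)
        # ceil(0.1 * 60) = 6 markers/chrom -> C(6,2)=15 pairs each
        assert len(pairs) + pairs.n_excluded_constant == n_chrom * 15
        # intra-chromosomal only: all distances within a chromosome span
        assert pairs.distance.max() < m_per * 10


class TestDecay:
    def test_constant_r2_never_crosses(self, rng):
        d = rng.uniform(1, 10000, 500)
        pairs = ld.LdPairSample(i=np.zeros(500, int), j=np.zeros(500, int),
                                distance=d, r2=np.full(500, 0.5),
                                fraction=0.1, seed=0)
        dec = ld.decay_summary(pairs, ref_distances=(1000,),
                               window_halfwidth_bp=500)
        assert dec.threshold_distance is None
        assert np.allclose(dec.fitted, 0.5, atol=1e-6)
        assert dec.windowed_means[1000] == pytest.approx(0.5)

    def test_planted_line_crossing(self, rng):
        """r^2 = max(0, 0.4 - d/10kb) crosses 0.2 at exactly 2 kb."""
        d = rng.uniform(1, 8000, 5000)
        pairs = ld.LdPairSample(i=np.zeros(5000, int), j=np.zeros(5000, int),
                                distance=d, r2=np.maximum(0, 0.4 - d / 10000),
                                fraction=0.1, seed=0)
        dec = ld.decay_summary(pairs, ref_distances=(1000,))
        assert dec.threshold_distance == pytest.approx(2000, rel=0.05)

    def test_windowed_means_decrease_on_simulated_panel(self, small_sim):
        pairs = ld.sample_pairs(small_sim.panel, fraction_per_chrom=0.3, seed=1)
        dec = ld.decay_summary(pairs, ref_distances=(1000, 100_000),
                               window_halfwidth_bp=2000)
        assert dec.windowed_means[1000] > dec.windowed_means[100_000]

    def test_threshold_grows_with_ld_decay_scale(self):
        def thr(decay):
            cfg = simdata.SimConfig(
                n_accessions=80, origin_counts={"A": 80}, n_families=1,
                progeny_per_family=1, n_chromosomes=2, n_snps_full=1200,
                n_snps_scaffold=100, chrom_length_bp=600_000,
                ld_decay_bp=decay, seed=9, n_environments=1)
            _, panel = simdata.simulate_founders(cfg)
            pairs = ld.sample_pairs(panel, fraction_per_chrom=0.5, seed=9)
            return ld.decay_summary(pairs, threshold_within_bp=20_000).threshold_distance

        assert thr(8_000) > thr(1_000)


class TestPrune:
    def test_independent_markers_all_retained(self, rng):
        # orthogonal-ish random markers at low correlation threshold won't
        # all survive; use strictly independent constructed columns instead
        base = np.tile(np.array([0, 1, 2, 0, 1, 2, 1, 0, 2, 1]), (3, 1)).T
        panel = _panel(np.column_stack([
            base[:, 0], np.roll(base[:, 0], 3), rng.permutation(base[:, 0])]))
        keep = ld.ld_prune(panel, window=10, step=5, r2_max=0.99)
        assert len(keep) == 3

    def test_duplicate_marker_removed(self):
        x = np.array([0, 1, 2, 0, 1, 2, 2, 0])
        y = np.array([1, 2, 0, 1, 2, 0, 2, 0])   # exactly uncorrelated with x
        panel = _panel(np.column_stack([x, x, y]))
        keep = ld.ld_prune(panel, window=3, step=1, r2_max=0.1)
        assert 0 in keep and 1 not in keep and 2 in keep

    def test_block_of_identical_markers_keeps_one(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 2])
        panel = _panel(np.tile(x[:, None], (1, 50)))
        keep = ld.ld_prune(panel, window=50, step=10, r2_max=0.1)
        assert len(keep) == 1 and keep[0] == 0

    def test_no_retained_pair_exceeds_threshold(self, small_sim):
        """Post-hoc exhaustive within-window check on a simulated panel."""
        panel = small_sim.panel
        keep = ld.ld_prune(panel, window=20, step=5, r2_max=0.2)
        keep_set = set(keep.tolist())
        for c in panel.chromosomes():
            idx = np.flatnonzero(panel.chrom == c)
            for start in range(0, len(idx), 5):
                win = [i for i in idx[start:start + 20] if i in keep_set]
                for a in range(len(win)):
                    for b in range(a + 1, len(win)):
                        da = panel.dosage[:, win[a]]
                        db = panel.dosage[:, win[b]]
                        if da.std() == 0 or db.std() == 0:
                            continue
                        assert ld.r2(da, db) <= 0.2 + 1e-9
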