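"""Heritability, variance decomposition, spatial adjustment, LS-means."""

import numpy as np
import pandas as pd
import pytest

from refpop import pheno, simdata
from refpop.datamodel import TreeRecordTable
from refpop.mixedlm import reml_oneway


def _table(rows):
    return TreeRecordTable(pd.DataFrame(
        rows, columns=["genotype", "environment", "block", "row", "col",
                       "trait", "value"]))


class TestHeritabilityFormulas:
    def test_individual_hand_arithmetic(self):
        """s2_g=3, s2_e=1, n_r=2 -> s2_p=3.5, H2=6/7."""
        s2_p, h2 = pheno.individual_h2(3.0, 1.0, 2.0)
        assert s2_p == pytest.approx(3.5)
        assert h2 == pytest.approx(3.0 / 3.5)

    def test_multi_location_hand_arithmetic(self):
        """s2_g=4, s2_gl=2, s2_e=2, n_l=5, n_r=2 -> s2_p=4.6, H2=0.870."""
        s2_p, h2 = pheno.multi_location_h2(4.0, 2.0, 2.0, 5, 2.0)
        assert s2_p == pytest.approx(4.6)
        assert h2 == pytest.approx(4.0 / 4.6)
        assert round(h2, 3) == 0.870

    def test_reported_s2p_reconstructs(self, study_sim):
        h = pheno.h2_individual(study_sim.phenotypes, "ENV1", "harvest")
        assert h.s2_p == pytest.approx(h.s2_g + h.s2_e / h.n_rep)
        vd, hm = pheno.fit_multienv(study_sim.phenotypes, "harvest",
                                    compute_ci=False)
        assert hm.s2_p == pytest.approx(
            hm.s2_g + hm.s2_gl / hm.n_loc + hm.s2_e / (hm.n_loc * hm.n_rep))


class TestRemlOracles:
    def test_balanced_equals_anova_closed_form(self):
        """REML on a balanced one-way design equals the method-of-moments
        ANOVA estimators (500 genotypes x 4 reps, true s2_g=2, s2_e=2)."""
        rng = np.random.default_rng(5)
        ng, r = 500, 4
        g = rng.normal(0, np.sqrt(2), ng)
        y = np.repeat(g, r) + rng.normal(0, np.sqrt(2), ng * r)
        groups = np.repeat(np.arange(ng), r)
        fit = reml_oneway(y, np.ones((ng * r, 1)), groups)
        gm = y.reshape(ng, r).mean(axis=1)
        msb = r * np.sum((gm - y.mean()) ** 2) / (ng - 1)
        mse = np.sum((y.reshape(ng, r) - gm[:, None]) ** 2) / (ng * (r - 1))
        assert fit.s2_u == pytest.approx((msb - mse) / r, abs=1e-6)
        assert fit.s2_e == pytest.approx(mse, abs=1e-6)

    def test_zero_residual_gives_h2_one(self):
        rows = [(f"g{i}", "E1", 1, i, 0, "t", float(i)) for i in range(10)]
        rows += [(f"g{i}", "E1", 2, i, 1, "t", float(i)) for i in range(10)]
        h = pheno.h2_individual(_table(rows))
        assert h.H2 == pytest.approx(1.0, abs=1e-6)

    def test_all_singletons_unidentifiable(self):
        rows = [(f"g{i}", "E1", 1, i, 0, "t", float(i)) for i in range(5)]
        with pytest.raises(ValueError, match="singleton"):
            pheno.h2_individual(_table(rows))


class TestMultiEnv:
    def test_parameter_recovery_is_within_tolerance(self, study_sim):
        vd, h2 = pheno.fit_multienv(study_sim.phenotypes, "harvest",
                                    compute_ci=False)
        spec = study_sim.config.trait_specs[0]
        assert abs(vd.fractions["genotype"] - spec.var_fraction_genotype) < 0.05
        assert abs(vd.fractions["environment"] - spec.var_fraction_environment) < 0.05
        assert abs(vd.fractions["gxe"] - spec.var_fraction_gxe) < 0.05

    def test_zero_gxe_ci_lower_bound_at_zero(self):
        rng = np.random.default_rng(2)
        rows = []
        g = rng.normal(0, 2, 40)
        for j, env in enumerate(["E1", "E2", "E3"]):
            l = [0.0, 1.0, -1.0][j]
            for i in range(40):
                for b in (1, 2):
                    rows.append((f"g{i}", env, b, (b - 1) * 40 + i, 0, "t",
                                 10 + g[i] + l + rng.normal(0, 1)))
        vd, _ = pheno.fit_multienv(_table(rows), "t")
        lo, hi = vd.confidence_intervals["gxe"]
        assert lo == pytest.approx(0.0, abs=1e-6)

    def test_needs_two_environments(self, study_sim):
        df = study_sim.phenotypes.df
        one = TreeRecordTable(df[df["environment"] == "ENV1"])
        with pytest.raises(ValueError, match="2 environments"):
            pheno.fit_multienv(one, "harvest")


class TestExclusionRule:
    def test_direct_rule(self):
        res = {f"E{i}": pheno.HeritabilityResult("individual-location", 0, 0, 1,
                                                 1, h) for i, h in
               enumerate([0.05, 0.6, 0.8])}
        assert pheno.exclude_low_h2(res) == ["E1", "E2"]

    def test_all_pass(self):
        res = {f"E{i}": pheno.HeritabilityResult("individual-location", 0, 0, 1,
                                                 1, h) for i, h in
               enumerate([0.2, 0.9])}
        assert pheno.exclude_low_h2(res) == ["E0", "E1"]

    def test_all_fail_raises(self):
        res = {"E0": pheno.HeritabilityResult("individual-location", 0, 0, 1, 1, 0.01)}
        with pytest.raises(ValueError):
            pheno.exclude_low_h2(res)

    def test_noise_environment_excluded_on_simulation(self):
        """A pure-noise environment among good ones is the one dropped."""
        rng = np.random.default_rng(4)
        g = rng.normal(0, 3, 50)
        rows = []
        for j in range(4):
            env = f"E{j}"
            for i in range(50):
                for b in (1, 2):
                    signal = 0.0 if j == 2 else g[i]
                    rows.append((f"g{i:02d}", env, b, (b - 1) * 50 + i, 0, "t",
                                 100 + signal + rng.normal(0, 1)))
        table = _table(rows)
        res = {e: pheno.h2_individual(table, e, "t") for e in table.environments()}
        keep = pheno.exclude_low_h2(res)
        assert keep == ["E0", "E1", "E3"]


class TestLsMeans:
    def test_balanced_hand_example(self):
        rows = [("A", "E1", 1, 0, 0, "t", 10.0), ("A", "E2", 1, 0, 0, "t", 20.0),
                ("B", "E1", 1, 1, 0, "t", 12.0), ("B", "E2", 1, 1, 0, "t", 26.0)]
        out = pheno.ls_means(_table(rows))
        lk = out.set_index("genotype")["lsmean"]
        assert lk["A"] == pytest.approx(15.0)
        assert lk["B"] == pytest.approx(19.0)

    def test_single_environment_equals_genotype_means(self):
        rows = [("A", "E1", 1, 0, 0, "t", 10.0), ("A", "E1", 1, 0, 1, "t", 14.0),
                ("B", "E1", 1, 1, 0, "t", 20.0)]
        out = pheno.ls_means(_table(rows)).set_index("genotype")["lsmean"]
        assert out["A"] == pytest.approx(12.0)
        assert out["B"] == pytest.approx(20.0)

    def test_unbalanced_matches_normal_equations(self):
        """A missing in E2: LS-mean of A = mu + g_A + mean(l), equal to the
        brute-force normal-equations solution."""
        rows = [("A", "E1", 1, 0, 0, "t", 10.0),
                ("B", "E1", 1, 1, 0, "t", 12.0), ("B", "E2", 1, 1, 1, "t", 26.0),
                ("C", "E1", 1, 2, 0, "t", 9.0), ("C", "E2", 1, 2, 1, "t", 21.0)]
        out = pheno.ls_means(_table(rows)).set_index("genotype")["lsmean"]
        # oracle: explicit OLS with treatment coding, first levels as baseline
        y = np.array([10, 12, 26, 9, 21], float)
        X = np.array([
            # mu gB gC lE2
            [1, 0, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 0, 1],
            [1, 0, 1, 0],
            [1, 0, 1, 1],
        ], float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        mu, gB, gC, lE2 = beta
        assert out["A"] == pytest.approx(mu + lE2 / 2)
        assert out["B"] == pytest.approx(mu + gB + lE2 / 2)
        assert out["C"] == pytest.approx(mu + gC + lE2 / 2)

    def test_reparameterization_invariance(self):
        """Adding a constant to one environment's values and later removing
        it from the environment effect leaves LS-means unchanged only when
        applied consistently; shifting ALL environments shifts LS-means by
        the mean shift."""
        rows = [("A", "E1", 1, 0, 0, "t", 10.0), ("A", "E2", 1, 0, 1, "t", 20.0),
                ("B", "E1", 1, 1, 0, "t", 12.0), ("B", "E2", 1, 1, 1, "t", 26.0)]
        base = pheno.ls_means(_table(rows)).set_index("genotype")["lsmean"]
        shifted = [(g, e, b, r, c, t, v + (7.0 if e == "E2" else 0.0))
                   for g, e, b, r, c, t, v in rows]
        out = pheno.ls_means(_table(shifted)).set_index("genotype")["lsmean"]
        assert np.allclose(out.values, base.values + 3.5)
        assert np.allclose(out["A"] - out["B"], base["A"] - base["B"])

    def test_disconnected_design_raises(self):
        rows = [("A", "E1", 1, 0, 0, "t", 10.0), ("B", "E2", 1, 1, 0, "t", 12.0)]
        with pytest.raises(ValueError, match="disconnected"):
            pheno.ls_means(_table(rows))


@pytest.fixture(scope="module")
def surface_sim():
    cfg = simdata.SimConfig(
        n_accessions=100, origin_counts={"A": 50, "B": 50}, n_families=10,
        progeny_per_family=5, n_chromosomes=5, n_snps_full=1500,
        n_snps_scaffold=150, n_environments=2, seed=11,
        trait_specs=[simdata.TraitSpec(
            "harvest", var_fraction_genotype=0.5,
            var_fraction_environment=0.05, var_fraction_gxe=0.1,
            var_fraction_spatial=0.25, var_fraction_residual=0.1)])
    return simdata.simulate_population(cfg)


class TestSpatial:
    def test_no_surface_no_noise_identity(self, small_sim):
        spec = simdata.TraitSpec("t0", var_fraction_genotype=1,
                                 var_fraction_environment=0, var_fraction_gxe=0,
                                 var_fraction_spatial=0, var_fraction_residual=0)
        table, _ = simdata.simulate_phenotypes(small_sim.panel, spec,
                                               n_environments=1, seed=3)
        _, adj = pheno.spatial_adjust(table, "ENV1", "t0")
        assert np.allclose(adj.df["value"], table.df["value"], atol=1e-6)

    def test_planted_surface_recovered(self, surface_sim):
        fit, _ = pheno.spatial_adjust(surface_sim.phenotypes, "ENV1", "harvest")
        df = surface_sim.phenotypes.df
        dfo = df[(df.environment == "ENV1") & (df.trait == "harvest")].reset_index(drop=True)
        truth = surface_sim.truth["harvest"].spatial["ENV1"]
        true_s = np.array([truth[r, c] for r, c in zip(dfo.row, dfo.col)])
        assert np.corrcoef(true_s, fit.spatial_total)[0, 1] >= 0.9

    def test_h2_not_decreased_by_adjustment(self, surface_sim):
        for env in ("ENV1", "ENV2"):
            _, adj = pheno.spatial_adjust(surface_sim.phenotypes, env, "harvest")
            raw = pheno.h2_individual(surface_sim.phenotypes, env, "harvest")
            cor = pheno.h2_individual(adj, env, "harvest")
            assert cor.H2 >= raw.H2 - 1e-6

    def test_single_column_layout_degrades_to_1d(self):
        rng = np.random.default_rng(0)
        rows = [(f"g{i % 20}", "E1", 1, i, 0, "t",
                 10 + 0.05 * i + rng.normal(0, 0.5)) for i in range(60)]
        with pytest.warns(UserWarning, match="1D"):
            fit, adj = pheno.spatial_adjust(_table(rows), "E1", "t")
        assert fit.notes

    def test_effective_dims_bounded_by_model_dimension(self, surface_sim):
        fit, _ = pheno.spatial_adjust(surface_sim.phenotypes, "ENV2", "harvest")
        n_trees = (surface_sim.phenotypes.df.environment == "ENV2").sum()
        assert sum(fit.effective_dims.values()) <= n_trees
        assert all(v >= -1e-6 for v in fit.effective_dims.values())
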