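"""Simulator unit and property tests: growth, mortality, stand dynamics."""

import numpy as np
import pytest

from gapcal.gapsim import (RECRUIT_DBH_CM, ClimateNormals, SiteConditions,
                           SpeciesParams, TreeRecord, annual_dbh_increment,
                           growing_degree_days, mortality_draws, run_stand,
                           step_mortality, synth_field_data)


class TestGrowingDegreeDays:
    def test_all_months_at_base_gives_zero(self):
        assert growing_degree_days([5.0] * 12, [30.0] * 12) == 0.0

    def test_single_warm_month(self):
        temps = [5.0] * 12
        temps[6] = 15.0
        days = [30.0] * 12
        assert growing_degree_days(temps, days) == pytest.approx(300.0)

    def test_cold_month_clamps_to_zero(self):
        temps = [5.0] * 12
        temps[0] = 4.0
        assert growing_degree_days(temps, [30.0] * 12) == 0.0

    @pytest.mark.parametrize("bad", [[5.0] * 11, [5.0] * 13])
    def test_wrong_length_rejected(self, bad):
        with pytest.raises(ValueError):
            growing_degree_days(bad, [30.0] * 12)


class TestAnnualIncrement:
    sp = SpeciesParams(name="X", g=0.2, dbh_min=0.0, dd_min=100.0, dmax=50.0)
    site = SiteConditions(resource_factor=1.0)

    def test_below_dd_min_gives_zero(self):
        assert annual_dbh_increment(10.0, self.sp, 50.0, self.site) == 0.0

    def test_at_dmax_gives_zero(self):
        assert annual_dbh_increment(50.0, self.sp, 500.0, self.site) == pytest.approx(0.0)

    def test_logistic_kernel_value(self):
        # g*D*(1 - D/dmax) = 0.2 * 10 * 0.8
        assert annual_dbh_increment(10.0, self.sp, 500.0, self.site) == pytest.approx(1.6)

    def test_gdd_offset_enters_gate(self):
        shifted = SiteConditions(resource_factor=1.0, gdd_offset=60.0)
        assert annual_dbh_increment(10.0, self.sp, 50.0, shifted) > 0.0

    def test_nonpositive_dbh_rejected(self):
        with pytest.raises(ValueError):
            annual_dbh_increment(0.0, self.sp, 500.0, self.site)


class TestSpeciesParamsInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"g": 0.0}, {"g": -1.0}, {"max_age": 0.0}, {"dmax": -5.0},
        {"p_stress": 0.2}, {"p_stress": 0.34}, {"recruit_rate": -1.0},
        {"dbh_min": -0.1}, {"dd_min": -1.0}, {"growth_sd": -0.2},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesParams(name="BAD", **kwargs)

    def test_background_mortality_convention(self):
        sp = SpeciesParams(name="X", max_age=200.0)
        assert sp.p_background == pytest.approx(4.605 / 200.0)


class TestMortality:
    def test_one_bad_year_only_background_risk(self):
        """A single below-minimum year must not trigger stress mortality."""
        sp = SpeciesParams(name="X", max_age=1e9, p_stress=0.33, dbh_min=0.5)
        dies, counters = mortality_draws(
            np.zeros(2000, dtype=int), sp, np.full(2000, 0.1),
            np.random.default_rng(0).random((2000, 2)),
        )
        assert not dies.any()
        assert (counters == 1).all()

    def test_background_survival_to_max_age(self):
        """~1% of an unstressed cohort survives to max_age (p_bg = 4.605/max_age)."""
        sp = SpeciesParams(name="X", max_age=200.0, dbh_min=0.0)
        rng = np.random.default_rng(42)
        n = 100_000
        alive = np.ones(n, dtype=bool)
        counters = np.zeros(n, dtype=int)
        for _ in range(200):
            idx = np.flatnonzero(alive)
            dies, counters[idx] = mortality_draws(
                counters[idx], sp, np.ones(len(idx)), rng.random((len(idx), 2))
            )
            alive[idx[dies]] = False
        expected = (1.0 - sp.p_background) ** 200  # ~= e^-4.605 ~= 0.01
        assert alive.mean() == pytest.approx(expected, abs=0.002)
        assert alive.mean() == pytest.approx(np.exp(-4.605), abs=0.004)

    def test_stressed_one_year_death_rate(self):
        """Stressed trees die at 1-(1-p_stress)(1-p_bg) per year."""
        sp = SpeciesParams(name="X", max_age=200.0, p_stress=0.25, dbh_min=1.0)
        rng = np.random.default_rng(3)
        n = 100_000
        dies, _ = mortality_draws(
            np.full(n, 2, dtype=int), sp, np.zeros(n), rng.random((n, 2))
        )
        closed_form = 1.0 - (1.0 - 0.25) * (1.0 - sp.p_background)
        assert dies.mean() == pytest.approx(closed_form, abs=0.005)

    def test_step_mortality_updates_tree(self):
        sp = SpeciesParams(name="X", max_age=50.0, dbh_min=0.5)
        tree = TreeRecord("t1", "X", 1, None, np.array([1.0, 1.2]), stress_counter=0)
        rng = np.random.default_rng(0)
        for year in range(3, 100):
            if not step_mortality(tree, sp, 0.1, rng, year=year):
                break
        assert tree.death_year is not None
        assert tree.stress_counter >= 1


class TestRunStand:
    def test_seeded_determinism(self, species_defaults, site, normals):
        a = run_stand(species_defaults, site, normals, 50, seed=9)
        b = run_stand(species_defaults, site, normals, 50, seed=9)
        assert len(a.trees) == len(b.trees)
        for ta, tb in zip(a.trees, b.trees):
            assert ta.tree_id == tb.tree_id
            assert ta.death_year == tb.death_year
            np.testing.assert_array_equal(ta.dbh_by_year, tb.dbh_by_year)
        for sp in a.species_ba_by_year:
            np.testing.assert_array_equal(
                a.species_ba_by_year[sp], b.species_ba_by_year[sp])

    def test_zero_recruitment_gives_empty_stand(self, site, normals):
        sp = SpeciesParams(name="X", recruit_rate=0.0)
        stand = run_stand([sp], site, normals, 30, seed=1)
        assert not stand.trees
        assert (stand.species_ba_by_year["X"] == 0).all()

    def test_ba_conservation(self, small_stand):
        """Stored species BA equals sum of pi*(dbh/2)^2 over alive trees."""
        recomputed = small_stand.recompute_ba()
        for sp, ba in small_stand.species_ba_by_year.items():
            np.testing.assert_allclose(recomputed[sp], ba, rtol=1e-9, atol=1e-9)

    def test_bare_ground_start(self, small_stand):
        assert all(t.birth_year >= 1 for t in small_stand.trees)
        year1 = [t for t in small_stand.trees if t.birth_year == 1]
        for t in year1:
            assert t.dbh_by_year[0] == RECRUIT_DBH_CM

    def test_years_below_one_rejected(self, species_defaults, site, normals):
        with pytest.raises(ValueError):
            run_stand(species_defaults, site, normals, 0, seed=1)

    def test_growth_monotone_in_g(self, site, normals):
        """Raising g never lowers any tree's DBH trajectory (same seed)."""
        lo = SpeciesParams(name="X", g=0.05, dbh_min=0.0, recruit_rate=4.0)
        hi = lo.replace(g=0.08)
        a = run_stand([lo], site, normals, 60, seed=5)
        b = run_stand([hi], site, normals, 60, seed=5)
        trees_a = {t.tree_id: t for t in a.trees}
        for tb in b.trees:
            ta = trees_a[tb.tree_id]
            n = min(len(ta.dbh_by_year), len(tb.dbh_by_year))
            assert (tb.dbh_by_year[:n] >= ta.dbh_by_year[:n] - 1e-12).all()

    def test_gdd_gate_blocks_all_growth(self, site, normals):
        """A species whose dd_min exceeds every realizable GDD never grows."""
        sp = SpeciesParams(name="X", dd_min=1e6, dbh_min=0.0, recruit_rate=4.0)
        stand = run_stand([sp], site, normals, 40, seed=2)
        for t in stand.trees:
            assert (t.dbh_by_year == RECRUIT_DBH_CM).all()


class TestSynthFieldData:
    def test_noise_free_equals_subset(self, small_stand):
        from gapcal.fading_proxy import alive_tree_subset
        fields = synth_field_data(small_stand, 60, sigma_eps=0.0, seed=0)
        subsets = alive_tree_subset(small_stand, 60)
        for sp, fs in fields.items():
            np.testing.assert_array_equal(fs.ba, subsets[sp].ba)

    def test_seeded_determinism(self, small_stand):
        a = synth_field_data(small_stand, 60, sigma_eps=50.0, seed=11)
        b = synth_field_data(small_stand, 60, sigma_eps=50.0, seed=11)
        for sp in a:
            np.testing.assert_array_equal(a[sp].ba, b[sp].ba)

    def test_noise_sd_matches_sigma(self, species_defaults, site, normals):
        """Empirical SD of (output - subset) over replicates approximates sigma."""
        from gapcal.fading_proxy import alive_tree_subset
        stand = run_stand(species_defaults, site, normals, 60, seed=4)
        subset = alive_tree_subset(stand, 60)
        sigma = 500.0
        diffs = []
        for rep in range(40):
            fields = synth_field_data(stand, 60, sigma_eps=sigma, seed=rep)
            for sp, fs in fields.items():
                base = subset[sp].ba
                mask = base > 5 * sigma  # clipping at zero distorts small-BA years
                diffs.append((fs.ba - base)[mask])
        diffs = np.concatenate(diffs)
        assert len(diffs) > 500
        assert diffs.std() == pytest.approx(sigma, rel=0.1)

    def test_truth_metadata_recorded(self, small_stand):
        fields = synth_field_data(small_stand, 60, sigma_eps=1.0, seed=0)
        for fs in fields.values():
            assert fs.truth["coring_year"] == 60
            assert "params" in fs.truth

    def test_out_of_range_coring_year(self, small_stand):
        with pytest.raises(ValueError):
            synth_field_data(small_stand, 500)
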