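"""Static comparator and the primary-education intervention."""

import numpy as np
import pytest

import microdem as md
from microdem.simulator import _newborn_distributions


class TestMakeStatic:
    def test_idempotent_and_levels_untouched(self, full_scenario):
        static = md.make_static(full_scenario.params)
        again = md.make_static(static)
        assert np.all(static.fertility.trend_F == 0)
        assert np.all(static.lee_carter.beta_year == 0)
        np.testing.assert_array_equal(static.fertility.F, full_scenario.params.fertility.F)
        np.testing.assert_array_equal(again.fertility.F, static.fertility.F)
        np.testing.assert_array_equal(again.migration.trend, static.migration.trend)

    def test_zero_length_horizon_identical(self, full_scenario):
        cfg = md.SimulationConfig(start_year=1992, end_year=1992)
        dyn = md.simulate(full_scenario.params, full_scenario.initial_state, cfg)
        stat = md.simulate(md.make_static(full_scenario.params), full_scenario.initial_state, cfg)
        np.testing.assert_array_equal(dyn.counts, stat.counts)

    def test_static_life_expectancy_lower_under_improving_mortality(self, full_scenario):
        """Freezing a negative mortality year-slope keeps hazards at their
        start-year level, so e0 trails the dynamic model every later year."""
        cfg = md.SimulationConfig(start_year=1992, end_year=2010)
        dyn = md.simulate(full_scenario.params, full_scenario.initial_state, cfg)
        static_params = md.make_static(full_scenario.params)
        stat = md.simulate(static_params, full_scenario.initial_state, cfg)
        le_dyn = md.period_life_expectancy(dyn, full_scenario.params)
        le_stat = md.period_life_expectancy(stat, static_params)
        assert np.all(le_stat[1:] < le_dyn[1:])
        assert le_stat[0] == pytest.approx(le_dyn[0], rel=1e-9)


class TestIntervention:
    def test_rural_mass_transfer(self, full_scenario):
        """After the intervention the rural no-schooling share moves into
        the 1-5-years category; the simplex is preserved."""
        params = md.apply_primary_education_intervention(full_scenario.params, 2000)
        before = _newborn_distributions(full_scenario.params, 2005)
        after = _newborn_distributions(params, 2005)
        rural = int(md.Residence.RURAL)
        urban = int(md.Residence.URBAN)
        assert after[rural, 0] == 0.0
        assert after[rural, 1] == pytest.approx(before[rural, 0] + before[rural, 1])
        np.testing.assert_allclose(after[rural, 2:], before[rural, 2:])
        np.testing.assert_allclose(after[urban], before[urban])
        assert after.sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_pre_intervention_cohorts_unchanged(self, full_scenario):
        params = md.apply_primary_education_intervention(full_scenario.params, 2000)
        np.testing.assert_allclose(
            _newborn_distributions(params, 1999),
            _newborn_distributions(full_scenario.params, 1999),
        )

    def test_original_params_not_mutated(self, full_scenario):
        md.apply_primary_education_intervention(full_scenario.params, 2000)
        assert full_scenario.params.education_intervention_year is None


class TestDiffInDiff:
    def test_identical_arms_give_zero(self):
        le = np.linspace(60, 70, 20)
        table = md.diff_in_diff_life_expectancy((le, le), (le, le))
        assert np.all(table["median"] == 0.0)
        assert np.all(table["lo95"] == 0.0)

    def test_static_equals_dynamic_cancels(self):
        rng = np.random.default_rng(0)
        base = 60 + rng.random((30, 20))
        lift = base + rng.random((30, 20))
        table = md.diff_in_diff_life_expectancy((base, lift), (base, lift))
        np.testing.assert_allclose(table["median"], 0.0, atol=1e-12)

    def test_horizon_mismatch_rejected(self):
        a, b = np.zeros(10), np.zeros(12)
        with pytest.raises(ValueError):
            md.diff_in_diff_life_expectancy((a, a), (b, b))


class TestFourArms:
    def test_common_random_numbers_zero_effect(self, full_scenario):
        """A no-op intervention (intervention after the horizon) produces
        bitwise-identical stochastic arms under a shared seed."""
        initial = full_scenario.initial_state.copy()
        initial.counts[:] = np.rint(initial.counts)
        cfg = md.SimulationConfig(
            start_year=1992, end_year=2000, mode="stochastic", seed=13
        )
        base = md.simulate(full_scenario.params, initial, cfg)
        norevent = md.apply_primary_education_intervention(full_scenario.params, 2050)
        other = md.simulate(norevent, initial, cfg)
        np.testing.assert_array_equal(base.counts, other.counts)

    def test_beneficial_intervention_non_negative_le_gain(self, full_scenario):
        """With mortality risk declining in education, universal primary
        education cannot reduce period life expectancy in either model."""
        cfg = md.SimulationConfig(start_year=1992, end_year=2015)
        arms = md.run_four_arms(full_scenario.params, full_scenario.initial_state, cfg, 2000)
        gain_dyn = arms["dynamic_intervention"].life_expectancy - arms["dynamic_base"].life_expectancy
        gain_stat = arms["static_intervention"].life_expectancy - arms["static_base"].life_expectancy
        assert np.all(gain_dyn >= -1e-9)
        assert np.all(gain_stat >= -1e-9)

    def test_static_overestimates_population_under_declining_trends(self, full_scenario):
        """Frozen (higher) fertility and mortality trends leave the static
        comparator with more people at the horizon's end."""
        cfg = md.SimulationConfig(start_year=1992, end_year=2020)
        arms = md.run_four_arms(full_scenario.params, full_scenario.initial_state, cfg, 2000)
        dyn_total = arms["dynamic_base"].trajectory.totals()[-1].sum()
        stat_total = arms["static_base"].trajectory.totals()[-1].sum()
        assert stat_total > dyn_total
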