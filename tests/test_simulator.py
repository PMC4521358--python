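"""Annual projection engine: competing risks, conservation, modes."""

import numpy as np
import pytest

import microdem as md
from microdem.params import default_template, neutralize
from microdem.state import MIG_NEVER, Residence


def simple_params(variant="v3", ref=2000, **overrides):
    ps = default_template(variant, reference_year=ref)
    for key, value in overrides.items():
        obj, fld = key.split(".")
        getattr(getattr(ps, obj), fld)[:] = value
    return ps


def uniform_state(year=2000, total=10000.0, age_max=60):
    state = md.PopulationState.empty(year)
    per = total / (age_max * 2 * 4)
    state.counts[:age_max, :, :, MIG_NEVER] = per
    return state


class TestCompetingRisks:
    def test_closed_form_two_hazards(self):
        """Death 0.01 + migration 0.02 split 1 - exp(-0.03) by hazard share."""
        p = md.competing_risk_probabilities([0.01, 0.02])
        np.testing.assert_allclose(p, [0.0098515, 0.0197030, 0.9704455], atol=5e-8)
        assert p.sum() == 1.0

    def test_zero_hazards(self):
        np.testing.assert_array_equal(md.competing_risk_probabilities([0.0, 0.0]), [0, 0, 1])

    def test_single_hazard_rate_to_probability(self):
        mu = 0.37
        p = md.competing_risk_probabilities([mu])
        assert p[0] == pytest.approx(1 - np.exp(-mu), rel=1e-12)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            md.competing_risk_probabilities([-0.01, 0.02])

    def test_matches_continuous_time_simulation(self):
        """Monte-Carlo oracle: first-event-type frequencies from exponential
        racing match the closed form."""
        rng = np.random.default_rng(42)
        n = 200_000
        t_death = rng.exponential(1 / 0.01, n)
        t_move = rng.exponential(1 / 0.02, n)
        death = np.mean((t_death < 1) & (t_death < t_move))
        move = np.mean((t_move < 1) & (t_move < t_death))
        p = md.competing_risk_probabilities([0.01, 0.02])
        assert death == pytest.approx(p[0], abs=3 * np.sqrt(p[0] / n))
        assert move == pytest.approx(p[1], abs=3 * np.sqrt(p[1] / n))


class TestStepYear:
    def test_zero_rates_pure_aging(self):
        """No mortality, fertility or migration: counts shift one age."""
        ps = simple_params("v1", **{"lee_carter.c": -40.0, "fertility.F": 1e-9})
        state = uniform_state()
        cfg = md.SimulationConfig(start_year=2000, end_year=2001, model_variant="v1")
        new, tallies = md.step_year(state, ps, cfg)
        np.testing.assert_allclose(new.counts[1:61], state.counts[0:60], rtol=1e-9)
        assert tallies["moves"] == 0.0
        assert tallies["deaths"] == pytest.approx(0.0, abs=1e-6)

    def test_conservation_identity(self):
        ps = simple_params("v3", **{"migration.base_rate": 0.01})
        state = uniform_state()
        cfg = md.SimulationConfig(start_year=2000, end_year=2001)
        new, tallies = md.step_year(state, ps, cfg)
        lhs = md.total_population(new)
        rhs = md.total_population(state) - tallies["deaths"] + tallies["births"]
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_stochastic_counts_are_integers(self):
        ps = simple_params("v3", **{"migration.base_rate": 0.01})
        state = uniform_state(total=9600)  # 20 women per occupied cell, integral
        cfg = md.SimulationConfig(start_year=2000, end_year=2001, mode="stochastic", seed=11)
        rng = np.random.default_rng(0)
        new, tallies = md.step_year(state, ps, cfg, rng)
        assert np.all(new.counts == np.rint(new.counts))
        total = md.total_population(state) - tallies["deaths"] + tallies["births"]
        assert md.total_population(new) == total  # exact integer bookkeeping


class TestSimulate:
    def test_degenerate_horizon(self):
        ps = simple_params("v1")
        state = uniform_state()
        traj = md.simulate(ps, state, md.SimulationConfig(start_year=2000, end_year=2000))
        assert len(traj.years) == 1

    def test_seed_reproducibility(self):
        ps = simple_params("v3", **{"migration.base_rate": 0.02})
        state = uniform_state(total=9600)
        cfg = md.SimulationConfig(start_year=2000, end_year=2010, mode="stochastic", seed=7)
        t1 = md.simulate(ps, state, cfg)
        t2 = md.simulate(ps, state, cfg)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_pure_migration_geometric_decay(self):
        """With only a rural-to-urban rate m, the rural cohort decays as
        exp(-m) per year."""
        m = 0.05
        ps = simple_params("v3", **{"lee_carter.c": -40.0, "fertility.F": 1e-9})
        ps.migration.base_rate[0, :] = m
        state = md.PopulationState.empty(2000)
        state.counts[20, Residence.RURAL, :, MIG_NEVER] = 250.0
        cfg = md.SimulationConfig(start_year=2000, end_year=2015)
        traj = md.simulate(ps, state, cfg)
        totals = traj.totals()
        t = np.arange(16)
        np.testing.assert_allclose(totals[:, Residence.RURAL], 1000.0 * np.exp(-m * t), rtol=1e-9)

    def test_migration_conserves_totals(self):
        ps = simple_params("v3", **{"lee_carter.c": -40.0, "fertility.F": 1e-9})
        ps.migration.base_rate[:, :] = 0.05
        state = uniform_state()
        cfg = md.SimulationConfig(start_year=2000, end_year=2020)
        traj = md.simulate(ps, state, cfg)
        np.testing.assert_allclose(traj.totals().sum(axis=1), md.total_population(state), rtol=1e-9)

    def test_annual_bookkeeping_over_horizon(self, full_scenario):
        traj = md.simulate(
            full_scenario.params,
            full_scenario.initial_state,
            md.SimulationConfig(start_year=1992, end_year=2010),
        )
        totals = traj.totals().sum(axis=1)
        for t in range(len(traj.years) - 1):
            expected = totals[t] - traj.deaths[t] + traj.births[t]
            assert totals[t + 1] == pytest.approx(expected, rel=1e-9)
        assert np.all(traj.counts >= 0)


class TestNesting:
    def test_neutralized_variants_reproduce_v1(self):
        """v2/v3 with unit RRs, tied fertility, zero migration and frozen
        education trends equal the v1 trajectory."""
        base = default_template("v3", reference_year=2000)
        base.fertility.F[:] = 3.0
        base.fertility.trend_F[:] = -0.02
        base.lee_carter.beta_year[:] = -0.02
        v1 = neutralize(base, "v1")
        state = uniform_state()
        trajs = {}
        for variant in ("v1", "v2", "v3"):
            ps = neutralize(base, variant)
            ps.education_rr.rr[:] = 1.0
            ps.migration.base_rate[:] = 0.0
            ps.migration.trend[:] = 0.0
            ps.education_trend.trend[:] = 0.0
            for fld in ("F", "a", "b", "trend_F"):
                arr = getattr(ps.fertility, fld)
                arr[:, :] = arr[:, :1]
            cfg = md.SimulationConfig(start_year=2000, end_year=2020, model_variant=variant)
            trajs[variant] = md.simulate(ps, state, cfg)
        np.testing.assert_allclose(trajs["v2"].counts, trajs["v1"].counts, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(trajs["v3"].counts, trajs["v1"].counts, rtol=1e-9, atol=1e-12)


class TestExtractOutcomes:
    def test_single_stratum_death_probability(self):
        """Uniform hazard mu gives band death probability 1 - exp(-mu)."""
        ps = default_template("v1", reference_year=2000)
        ps.lee_carter.c[:] = np.log(0.02)
        ps.lee_carter.beta_age[:] = 0.0
        ps.lee_carter.beta_year[:] = 0.0
        state = uniform_state()
        cfg = md.SimulationConfig(start_year=2000, end_year=2002)
        traj = md.simulate(ps, state, cfg)
        import pandas as pd

        rows = pd.DataFrame(
            [
                {
                    "class": "mortality",
                    "year": 2001,
                    "age_low": 15,
                    "age_high": 24,
                    "residence": "rural",
                    "education": "all",
                    "window": "",
                    "estimate": 0.02,
                    "ci_low": 0.01,
                    "ci_high": 0.03,
                    "calibration": True,
                }
            ]
        )
        ts = md.TargetSet(rows)
        out = md.extract_outcomes(traj, ts, ps)
        assert out.values[0] == pytest.approx(1 - np.exp(-0.02), rel=1e-9)

    def test_education_prevalence_and_population(self, full_scenario, exact_targets):
        """Zero-noise targets equal the truth's extracted outcomes, and the
        population rows match stratum totals."""
        targets, _ = exact_targets
        traj = md.simulate(
            full_scenario.params, full_scenario.initial_state, full_scenario.sim_config
        )
        out = md.extract_outcomes(traj, targets, full_scenario.params)
        est = targets.df["estimate"].to_numpy(float)
        np.testing.assert_allclose(out.values, est, rtol=1e-9, atol=1e-12)
        pop_rows = targets.df["class"] == "population_size"
        years = targets.df.loc[pop_rows, "year"]
        totals = traj.totals()
        for value, (year, res) in zip(
            out.values[pop_rows.to_numpy()],
            zip(years, targets.df.loc[pop_rows, "residence"]),
        ):
            t = int(year) - 1992
            assert value == pytest.approx(totals[t, 0 if res == "urban" else 1], rel=1e-12)

    def test_target_year_outside_horizon_rejected(self, full_scenario, exact_targets):
        targets, _ = exact_targets
        cfg = md.SimulationConfig(start_year=1992, end_year=1995)
        traj = md.simulate(full_scenario.params, full_scenario.initial_state, cfg)
        with pytest.raises(ValueError):
            md.extract_outcomes(traj, targets, full_scenario.params)
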