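"""Synthetic ground truths and survey-style target generation."""

import warnings

import numpy as np
import pytest

import microdem as md
from microdem.calibration import Chain
from microdem.params import VariantSpec


class TestMakeTruth:
    def test_static_scenario_zeroes_all_trends(self):
        sc = md.make_truth("static", seed=0)
        assert np.all(sc.params.fertility.trend_F == 0)
        assert np.all(sc.params.lee_carter.beta_year == 0)
        assert np.all(sc.params.migration.trend == 0)
        assert np.all(sc.params.education_trend.trend == 0)

    def test_full_effects_orderings(self):
        """Mortality risk falls and migration rises with education."""
        sc = md.make_truth("full_effects", seed=0)
        rr = sc.params.education_rr.rr
        assert np.all(np.diff(rr, axis=1) < 0)
        assert np.all(np.diff(sc.params.migration.base_rate[0]) > 0)
        assert np.all(sc.params.fertility.trend_F < 0)
        assert np.all(sc.params.lee_carter.beta_year < 0)

    def test_no_education_effects_neutralized(self):
        sc = md.make_truth("no_education_effects", seed=0)
        assert np.all(sc.params.education_rr.rr == 1.0)
        assert np.all(sc.params.education_trend.trend == 0.0)
        f = sc.params.fertility.F
        assert np.all(f == f[:, :1])

    def test_deterministic_given_name_and_seed(self):
        a = md.make_truth("full_effects", seed=5)
        b = md.make_truth("full_effects", seed=5)
        np.testing.assert_array_equal(a.initial_state.counts, b.initial_state.counts)
        np.testing.assert_array_equal(a.params.fertility.F, b.params.fertility.F)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            md.make_truth("bogus", seed=0)


class TestGenerateTargets:
    def test_zero_noise_targets_equal_truth(self, full_scenario, exact_targets):
        """With noise off, the likelihood is maximized at the truth."""
        targets, initial = exact_targets
        traj = md.simulate(full_scenario.params, initial, full_scenario.sim_config)
        out = md.extract_outcomes(traj, targets, full_scenario.params)
        np.testing.assert_allclose(out.values, targets.df["estimate"].to_numpy(float), rtol=1e-9)
        ll_truth = md.log_likelihood(out.values, targets)
        ll_off = md.log_likelihood(out.values * 1.01, targets)
        assert ll_truth > ll_off

    def test_reproducible_bit_for_bit(self, full_scenario):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1, _ = md.generate_targets(full_scenario)
            t2, _ = md.generate_targets(full_scenario)
        np.testing.assert_array_equal(
            t1.df["estimate"].to_numpy(), t2.df["estimate"].to_numpy()
        )

    def test_ci_coverage_near_95_percent(self, full_scenario, exact_targets):
        """Written intervals cover the truth at their nominal rate."""
        exact, _ = exact_targets
        truth_vals = exact.df["estimate"].to_numpy(float)
        covered = []
        for seed in range(8):
            sc = md.make_truth("full_effects", seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                noisy, _ = md.generate_targets(sc)
            df = noisy.df[noisy.df["calibration"]]
            idx = df.index.to_numpy()
            covered.append(
                (df["ci_low"].to_numpy() <= truth_vals[idx])
                & (truth_vals[idx] <= df["ci_high"].to_numpy())
            )
        rate = np.concatenate(covered).mean()
        assert rate == pytest.approx(0.95, abs=0.02)

    def test_migration_windows_nested(self, full_targets):
        """moved-within-6y <= within-12y <= ever for every stratum."""
        targets, _ = full_targets
        mig = targets.df[targets.df["class"] == "migration"]
        pivot = mig.pivot_table(
            index=["year", "residence", "education", "age_low"],
            columns="window",
            values="estimate",
        )
        assert np.all(pivot["6y"] <= pivot["12y"] + 1e-12)
        assert np.all(pivot["12y"] <= pivot["ever"] + 1e-12)

    def test_generated_files_validate_cleanly(self, tmp_path, full_scenario):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            # the default noise occasionally truncates at zero, which warns;
            # catch only unexpected warnings by allowing that one
            warnings.filterwarnings("ignore", message=".*truncated at zero")
            manifest = md.write_scenario(full_scenario, tmp_path)
            loaded = md.load_targets(manifest)
        assert len(loaded) > 0


class TestRecoveryReport:
    def test_point_mass_at_truth_is_fully_covered(self, full_scenario):
        spec = VariantSpec("v3")
        truth = spec.to_vector(full_scenario.params)
        chain = Chain(
            draws=np.tile(truth, (50, 1)),
            deviance=np.zeros(50),
            names=spec.names,
            accept_rate=0.5,
            seed=0,
            burn_in=0,
        )
        rep = md.recovery_report([chain], full_scenario)
        assert rep.attrs["coverage"] == 1.0
        assert np.allclose(rep["relative_error"], 0.0)

    def test_shifted_chain_not_covered(self, full_scenario):
        spec = VariantSpec("v3")
        truth = spec.to_vector(full_scenario.params)
        rng = np.random.default_rng(0)
        draws = truth + 0.001 * rng.standard_normal((200, truth.size)) + 10.0
        chain = Chain(
            draws=draws, deviance=np.zeros(200), names=spec.names,
            accept_rate=0.5, seed=0, burn_in=0,
        )
        rep = md.recovery_report([chain], full_scenario)
        assert not rep["covered"].any()

    def test_name_mismatch_rejected(self, full_scenario):
        chain = Chain(
            draws=np.zeros((10, 3)), deviance=np.zeros(10), names=["a", "b", "c"],
            accept_rate=0.5, seed=0, burn_in=0,
        )
        with pytest.raises(ValueError):
            md.recovery_report([chain], full_scenario)
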