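"""ELISA arithmetic, dose-response fitting and decay summarization."""

import numpy as np
import pytest

import triazopep as tp


class TestPercentInhibition:
    def test_boundary_identities(self):
        assert tp.percent_inhibition(S=1.0, NS=0.05, Pmax=1.0) == \
            pytest.approx(0.0)
        assert tp.percent_inhibition(S=0.05, NS=0.05, Pmax=1.0) == \
            pytest.approx(100.0)

    def test_inverts_to_the_printed_best_compound_value(self):
        # S placed 41.9% of the way up the window corresponds to 58.1%
        NS, Pmax = 0.1, 0.9
        S = NS + 0.419 * (Pmax - NS)
        assert tp.percent_inhibition(S, NS, Pmax) == pytest.approx(58.1)

    def test_affine_invariance_of_joint_signal_transform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            S, NS, Pmax = rng.uniform(0.1, 1.0, 3)
            if Pmax == NS:
                continue
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-1.0, 1.0)
            assert tp.percent_inhibition(a * S + b, a * NS + b,
                                         a * Pmax + b) == \
                pytest.approx(tp.percent_inhibition(S, NS, Pmax))

    def test_strictly_decreasing_in_signal(self):
        s = np.linspace(0.05, 1.0, 10)
        inh = tp.percent_inhibition(s, 0.05, 1.0)
        assert np.all(np.diff(inh) < 0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            tp.percent_inhibition(0.5, 0.3, 0.3)


class TestReplicates:
    def test_mean_and_sample_sd(self):
        assert tp.summarize_replicates([58.1, 58.1]) == (58.1, 0.0)
        mean, sd = tp.summarize_replicates([56, 58, 60])
        assert mean == pytest.approx(58) and sd == pytest.approx(2)

    def test_matches_two_pass_variance_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.normal(50, 5, size=int(rng.integers(2, 12)))
            mean, sd = tp.summarize_replicates(v)
            m = sum(v) / len(v)
            var = sum((x - m) ** 2 for x in v) / (len(v) - 1)
            assert mean == pytest.approx(m)
            assert sd == pytest.approx(var ** 0.5)

    def test_single_value_flagged_with_nan_sd(self):
        mean, sd = tp.summarize_replicates([42.0])
        assert mean == 42.0 and np.isnan(sd)


class TestDoseResponse:
    def test_noiseless_curve_recovered_exactly(self):
        curve = tp.gen_dose_response(log_ic50=-5.076, hill=1.0, sigma=0.0)
        fit = tp.fit_dose_response(curve["conc_molar"], curve["inh"])
        assert fit.log_ic50 == pytest.approx(-5.076, abs=1e-8)
        assert fit.hill == pytest.approx(1.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.ic50_micromolar == pytest.approx(8.39, abs=0.005)

    def test_round_trip_regenerates_inputs(self):
        curve = tp.gen_dose_response(log_ic50=-5.5, hill=1.3, sigma=0.0)
        fit = tp.fit_dose_response(curve["conc_molar"], curve["inh"])
        assert np.allclose(fit.curve(curve["conc_molar"]), curve["inh"],
                           atol=1e-8)

    def test_fixed_hill_mode(self):
        curve = tp.gen_dose_response(log_ic50=-5.0, hill=1.0, sigma=0.0)
        fit = tp.fit_dose_response(curve["conc_molar"], curve["inh"],
                                   fix_hill=1.0)
        assert fit.hill == 1.0 and fit.hill_se is None
        assert fit.log_ic50 == pytest.approx(-5.0, abs=1e-8)

    def test_noisy_recovery_within_three_se(self):
        """At 5 percentage points of noise over 8 concentrations, the
        mean absolute logIC50 error stays below 3x the mean reported SE."""
        errors, ses = [], []
        for seed in range(200):
            curve = tp.gen_dose_response(log_ic50=-5.076, hill=1.0,
                                         sigma=5.0, seed=seed)
            fit = tp.fit_dose_response(curve["conc_molar"], curve["inh"])
            errors.append(abs(fit.log_ic50 + 5.076))
            ses.append(fit.log_ic50_se)
        assert np.mean(errors) < 3 * np.mean(ses)

    def test_monotone_in_generating_ic50(self):
        fitted = []
        for l50 in (-6.0, -5.5, -5.0, -4.5):
            curve = tp.gen_dose_response(log_ic50=l50, sigma=0.0)
            fit = tp.fit_dose_response(curve["conc_molar"], curve["inh"])
            fitted.append(fit.ic50_micromolar)
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            tp.fit_dose_response([1e-6, 1e-5], [20, 80])


class TestIc50Conversion:
    @pytest.mark.parametrize("log_ic50,um", [
        (-5.076, 8.39), (-6.0, 1.00), (-5.0, 10.00),
    ])
    def test_antilog_to_micromolar(self, log_ic50, um):
        assert tp.ic50_micromolar(log_ic50) == pytest.approx(um, abs=0.005)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tp.ic50_micromolar(float("nan"))


class TestDecay:
    def test_exact_half_life_recovered(self):
        ser = tp.gen_decay_series(half_life_h=48.0, sigma=0.0)
        fit = tp.fit_decay(ser["time_h"], ser["fraction"])
        assert not fit.censored
        assert fit.half_life_h == pytest.approx(48.0, abs=1e-6)

    def test_flat_series_censored_at_window_end(self):
        ser = tp.gen_decay_series(half_life_h=np.inf, sigma=0.0)
        fit = tp.fit_decay(ser["time_h"], ser["fraction"])
        assert fit.censored and fit.k == 0.0
        assert fit.half_life_h == 48.0

    def test_slow_decay_below_resolution_censored(self):
        # t1/2 = 1000 h declines ~3% over 48 h, under the 10-point default
        ser = tp.gen_decay_series(half_life_h=1000.0, sigma=0.0)
        fit = tp.fit_decay(ser["time_h"], ser["fraction"])
        assert fit.censored
        assert fit.half_life_h == 48.0

    def test_noisy_recovery_over_seeds(self):
        ks = []
        true_k = np.log(2) / 30.0
        for seed in range(200):
            ser = tp.gen_decay_series(half_life_h=30.0, sigma=2.0, seed=seed)
            ks.append(tp.fit_decay(ser["time_h"], ser["fraction"]).k)
        assert np.mean(ks) == pytest.approx(true_k, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tp.fit_decay([-1, 0, 8], [100, 100, 90])
        with pytest.raises(ValueError):
            tp.fit_decay([8, 16, 24], [90, 80, 70])  # no t=0 anchor
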