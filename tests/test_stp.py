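import numpy as np
import pytest
from scipy import stats

from emcscreen import observer, preprocess, stp
from emcscreen.observer import ObserverModel
from emcscreen.stp import (
    FEATURE_NAMES,
    FitError,
    average_correlograms,
    cosine_similarity,
    cross_correlogram,
    extract_features,
    fit_gaussian,
    observation_noise_variance,
    positional_error_distribution,
)
from emcscreen.stimulus import SessionConfig, generate_trajectory

from conftest import make_clean_trials


def pearson_oracle(stim_vel, gaze_vel, rate, max_lag=1.0):
    """Direct per-lag Pearson correlation via scipy, the reference."""
    n = len(stim_vel)
    L = int(round(max_lag * rate))
    lags, r = [], []
    for k in range(-L, L + 1):
        if k >= 0:
            a, b = gaze_vel[k:], stim_vel[: n - k]
        else:
            a, b = gaze_vel[: n + k], stim_vel[-k:]
        lags.append(k / rate)
        r.append(stats.pearsonr(a, b).statistic)
    return np.array(lags), np.array(r)


class TestCrossCorrelogram:
    def test_identical_series_peak_at_zero_with_r_one(self, rng):
        v = rng.normal(0, 1, 600)
        ccg = cross_correlogram(v, v, rate=60.0)
        assert ccg.peak_lag == 0.0
        assert ccg.r[ccg.lags == 0.0][0] == pytest.approx(1.0)
        assert np.all(ccg.r <= 1.0 + 1e-12)

    def test_pure_delay_recovers_the_shift(self, rng):
        v = rng.normal(0, 1, 1200)
        delayed = np.concatenate((np.zeros(10), v[:-10]))
        ccg = cross_correlogram(v, delayed, rate=60.0)
        assert ccg.peak_lag == pytest.approx(10 / 60.0)
        assert ccg.r.max() > 0.99

    def test_lag_grid_spans_plus_minus_one_second(self, rng):
        ccg = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300),
                                rate=60.0)
        assert ccg.lags[0] == -1.0 and ccg.lags[-1] == 1.0
        assert np.allclose(np.diff(ccg.lags), 1 / 60.0)
        np.testing.assert_allclose(ccg.lags, -ccg.lags[::-1])

    def test_white_noise_null_stays_small(self):
        """Independent series of length 1200: max |r| < 0.15 almost always."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            ccg = cross_correlogram(rng.normal(0, 1, 1200),
                                    rng.normal(0, 1, 1200), rate=60.0)
            hits += np.abs(ccg.r).max() < 0.15
        assert hits / n_sim >= 0.98

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_correlogram(rng.normal(0, 1, 100), rng.normal(0, 1, 100),
                              rate=60.0, max_lag=1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_correlogram(np.zeros(300), np.ones(300), rate=60.0)

    def test_matches_direct_pearson_oracle(self, rng):
        """Implementation equals per-lag scipy.stats.pearsonr to 1e-10."""
        for _ in range(50):
            s = rng.normal(0, 1, 200)
            g = 0.5 * s + rng.normal(0, 1, 200)
            ccg = cross_correlogram(s, g, rate=60.0, max_lag=0.5)
            lags, r = pearson_oracle(s, g, 60.0, 0.5)
            np.testing.assert_allclose(ccg.lags, lags, atol=1e-12)
            np.testing.assert_allclose(ccg.r, r, atol=1e-10)


class TestAverageCorrelograms:
    def test_identical_inputs_average_to_themselves(self, rng):
        c = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300),
                              rate=60.0)
        avg = average_correlograms([c, c, c])
        np.testing.assert_allclose(avg.r, c.r)

    def test_pointwise_mean_of_two(self, rng):
        a = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300), 60.0)
        b = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300), 60.0)
        avg = average_correlograms([a, b])
        np.testing.assert_allclose(avg.r, (a.r + b.r) / 2)

    def test_peak_of_mean_lies_between_individual_peaks(self, rng):
        v = rng.normal(0, 1, 1200)
        ccgs = []
        for shift in (5, 9):
            g = np.concatenate((np.zeros(shift), v[:-shift]))
            ccgs.append(cross_correlogram(v, g, 60.0))
        peak = average_correlograms(ccgs).peak_lag
        assert 5 / 60.0 <= peak <= 9 / 60.0

    def test_empty_and_mismatched_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            average_correlograms([])
        a = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300), 60.0)
        b = cross_correlogram(rng.normal(0, 1, 300), rng.normal(0, 1, 300),
                              60.0, max_lag=0.5)
        with pytest.raises(ValueError):
            average_correlograms([a, b])


class TestFitGaussian:
    def test_exact_gaussian_recovered_to_1e6(self):
        x = np.linspace(-1, 1, 121)
        y = 0.8 * np.exp(-((x - 0.2) ** 2) / (2 * 0.05**2))
        fit = fit_gaussian(x, y)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)
        assert fit.mean == pytest.approx(0.2, abs=1e-6)
        assert fit.sd == pytest.approx(0.05, abs=1e-6)
        assert fit.adj_r2 > 0.999999

    def test_flat_input_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian(np.linspace(0, 1, 50), np.zeros(50))

    def test_noisy_gaussian_within_5pct(self, rng):
        x = np.linspace(-1, 1, 121)
        y = 0.8 * np.exp(-((x - 0.2) ** 2) / (2 * 0.1**2))
        y = y + rng.normal(0, 0.008, x.size)
        fit = fit_gaussian(x, y)
        assert fit.amplitude == pytest.approx(0.8, rel=0.05)
        assert fit.mean == pytest.approx(0.2, abs=0.05 * 0.2 + 0.01)
        assert fit.sd == pytest.approx(0.1, rel=0.05)
        assert fit.adj_r2 > 0.99

    def test_mean_constrained_to_x_range(self, rng):
        x = np.linspace(0, 1, 50)
        y = np.exp(-((x + 2.0) ** 2))  # peak far left of the window
        fit = fit_gaussian(x, y + rng.normal(0, 1e-4, 50))
        assert 0.0 <= fit.mean <= 1.0


class TestPositionalErrorDistribution:
    def test_perfect_tracking_concentrates_in_the_zero_bin(self):
        ped = positional_error_distribution(np.zeros(5000))
        assert ped.probability.sum() == pytest.approx(1.0, abs=1e-9)
        assert ped.probability[np.abs(ped.bin_centers) < 0.25][0] == 1.0
        assert ped.fit.sd < 0.5

    def test_constant_offset_shifts_the_fitted_mean(self, rng):
        errors = 1.5 + rng.normal(0, 0.3, 7200)
        ped = positional_error_distribution(errors)
        assert ped.fit.mean == pytest.approx(1.5, abs=0.25)

    def test_noise_sd_recovered_within_10pct(self, rng):
        ped = positional_error_distribution(rng.normal(0, 2.0, 7200))
        assert ped.fit.sd == pytest.approx(2.0, rel=0.10)

    def test_unit_mass(self, rng):
        ped = positional_error_distribution(rng.normal(0, 1, 500))
        assert ped.probability.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            positional_error_distribution(np.array([np.nan]))


class TestCosineSimilarity:
    def test_identical_vectors_give_one(self, rng):
        v = rng.normal(0, 3, 500)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        a = np.array([1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 1.0])
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        v = rng.normal(0, 3, 500)
        assert cosine_similarity(v, 2.0 * v) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(10), np.ones(10))


class TestObservationNoiseVariance:
    def _stim(self, seconds=120.0, seed=3):
        cfg = SessionConfig(trial_duration=seconds, seed=seed)
        return generate_trajectory(cfg, "smooth")

    def test_exact_gaze_gives_near_zero_noise(self):
        s = self._stim().x
        est = observation_noise_variance(s, s.copy())
        assert est.observation_noise_variance < 1e-6

    def test_known_noise_recovered_within_20pct(self):
        s = self._stim().x
        rng = np.random.default_rng(4)
        y = s + rng.normal(0, 1.0, s.size)
        est = observation_noise_variance(s, y)
        assert est.observation_noise_variance == pytest.approx(1.0, rel=0.20)

    def test_estimate_is_monotone_in_true_noise(self):
        s = self._stim().x
        rng = np.random.default_rng(5)
        estimates = [
            observation_noise_variance(
                s, s + rng.normal(0, np.sqrt(r), s.size)
            ).observation_noise_variance
            for r in (0.25, 1.0, 4.0)
        ]
        assert estimates[0] < estimates[1] < estimates[2]

    def test_matches_statsmodels_local_level(self):
        """Cross-check against the independent state-space implementation."""
        sm = pytest.importorskip("statsmodels.tsa.statespace.structural")
        s = self._stim(seconds=40.0).x
        rng = np.random.default_rng(6)
        y = s + rng.normal(0, 0.8, s.size)
        est = observation_noise_variance(s, y)
        model = sm.UnobservedComponents(y, level="llevel")
        with model.fix_params({"sigma2.level": est.target_displacement_variance}):
            fitted = model.fit(disp=False)
        r_sm = float(fitted.params[fitted.param_names.index("sigma2.irregular")])
        assert est.observation_noise_variance == pytest.approx(r_sm, rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            observation_noise_variance(np.zeros(50), np.zeros(50))


class TestExtractFeatures:
    def test_identity_observer_features(self, identity_observer):
        smooth = make_clean_trials(identity_observer, "smooth", n_trials=3, seed=1)
        disp = make_clean_trials(identity_observer, "displaced", n_trials=3, seed=2)
        f = extract_features(smooth, disp)
        for mode in ("smooth", "displaced"):
            for axis in ("horizontal", "vertical"):
                assert f[f"cosine_similarity_{axis}_{mode}"] == pytest.approx(1.0)
                assert abs(f[f"ccg_mean_{axis}_{mode}"]) < 1 / 60.0

    def test_exactly_40_named_entries_in_canonical_order(self, quiet_observer):
        smooth = make_clean_trials(quiet_observer, "smooth", n_trials=2, seed=3)
        disp = make_clean_trials(quiet_observer, "displaced", n_trials=2, seed=4)
        f = extract_features(smooth, disp)
        assert len(f.values) == 40
        assert list(f.values) == sorted(f.values, key=list(FEATURE_NAMES).index)
        assert FEATURE_NAMES[0] == "ped_amplitude_horizontal_smooth"
        assert FEATURE_NAMES[1] == "ped_amplitude_horizontal_displaced"
        assert FEATURE_NAMES[2] == "ped_amplitude_vertical_smooth"

    def test_lagged_observer_smooth_ccg_mean_recovered(self):
        obs = ObserverModel(lag=0.2, noise_sd=0.5, blink_rate=0.0)
        smooth = make_clean_trials(obs, "smooth", seed=5)
        disp = make_clean_trials(obs, "displaced", n_trials=2, seed=6)
        f = extract_features(smooth, disp)
        for axis in ("horizontal", "vertical"):
            assert f[f"ccg_mean_{axis}_smooth"] == pytest.approx(0.2, abs=1 / 60.0)

    def test_bounded_ranges_hold_on_a_simulated_cohort(self):
        """PED amplitude and cosine in [0,1]; CCG amplitude in [-1,1]; adj R² ≤ 1."""
        cohort = observer.generate_cohort(
            observer.default_phenotypes(2, 2, 2),
            SessionConfig(n_trials=2, trial_duration=10.0, seed=0), seed=0,
        )
        for p in cohort:
            trials = {
                m: [preprocess.preprocess_trial(g, s) for s, g in p.sessions[m]]
                for m in ("smooth", "displaced")
            }
            f = extract_features(trials["smooth"], trials["displaced"])
            for key in FEATURE_NAMES:
                v = f[key]
                if not np.isfinite(v):
                    continue
                if key.startswith(("ped_amplitude", "cosine_similarity")):
                    assert 0.0 <= v <= 1.0
                elif key.startswith("ccg_amplitude"):
                    assert -1.0 <= v <= 1.0
                elif "adj_r2" in key:
                    assert v <= 1.0
                elif key.startswith(("ped_mean", "ped_sd", "ccg_sd",
                                     "noise_variance")):
                    assert v >= 0.0

    def test_all_invalid_trials_rejected(self, quiet_observer):
        trials = make_clean_trials(quiet_observer, "smooth", n_trials=2, seed=7)
        for t in trials:
            t.valid = False
        disp = make_clean_trials(quiet_observer, "displaced", n_trials=2, seed=8)
        with pytest.raises(ValueError):
            extract_features(trials, disp)
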