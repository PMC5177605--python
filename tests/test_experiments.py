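"""Protocol experiments and LFP spike/frequency/settling analysis."""
import numpy as np
import pytest

from gliamass import (
    InputSpec,
    default_params,
    detect_spikes,
    gaba_bolus_experiment,
    p_snic_trace,
    settle_time,
    spike_frequency,
    uptake_deficiency_experiment,
)
from gliamass.experiments import default_input, ensemble_settle_time, mean_rate
from gliamass.io import make_fixture_lfp
from gliamass.bifurcation import p_snic
from gliamass.simulate import integrate


class TestDetectSpikes:
    def test_constant_series_has_no_spikes(self):
        t = np.arange(0, 10, 1e-3)
        assert len(detect_spikes(t, np.full_like(t, 1.2))) == 0

    def test_pure_noise_has_no_spikes(self):
        t, series, _ = make_fixture_lfp(0, noise_sd=0.5, seed=3)
        assert len(detect_spikes(t, series)) == 0

    @pytest.mark.parametrize("n_spikes", [1, 5, 12])
    def test_recovers_noiseless_bumps_within_one_sample(self, n_spikes):
        t, series, truth = make_fixture_lfp(n_spikes, amplitude=10, noise_sd=1e-9, seed=1)
        found = detect_spikes(t, series, threshold=5.0)
        assert len(found) == n_spikes
        dt = t[1] - t[0]
        assert np.max(np.abs(found - truth)) <= dt + 1e-12

    @pytest.mark.parametrize("n_spikes", [1, 5, 12])
    def test_recovers_noisy_bumps_near_their_peaks(self, n_spikes):
        t, series, truth = make_fixture_lfp(n_spikes, amplitude=10, noise_sd=0.4, seed=1)
        found = detect_spikes(t, series)
        assert len(found) == n_spikes
        # argmax jitter from noise on the rounded bump top stays well
        # inside the bump width
        assert np.max(np.abs(found - truth)) <= 0.02

    def test_refractory_merges_close_bumps(self):
        t = np.arange(0, 4, 1e-3)
        series = np.zeros_like(t)
        for tc in (2.0, 2.05):  # closer than min_isi
            series += 10 * np.exp(-0.5 * ((t - tc) / 0.01) ** 2)
        found = detect_spikes(t, series, threshold=5.0, min_isi=0.2)
        assert len(found) == 1

    def test_fixed_threshold_and_baseline_window(self):
        t, series, truth = make_fixture_lfp(3, amplitude=8, noise_sd=0.3, seed=5)
        a = detect_spikes(t, series, threshold=4.0)
        b = detect_spikes(t, series, baseline=(0.0, t[-1]))
        assert len(a) == len(b) == 3


class TestSpikeFrequency:
    def test_empty_train_is_zero(self):
        grid, freq = spike_frequency(np.array([]), window=5.0, span=(0, 50))
        assert np.all(freq == 0)

    def test_periodic_train_recovers_rate(self):
        period = 0.5
        spikes = np.arange(0, 100, period)
        grid, freq = spike_frequency(spikes, window=20.0, span=(20, 80))
        np.testing.assert_allclose(freq, 1 / period, rtol=0.05)

    def test_doubling_window_halves_poisson_variance(self):
        # Monte-Carlo over seeds on a homogeneous Poisson train
        rate = 2.0
        var = {}
        for window in (5.0, 10.0):
            centers = []
            for seed in range(40):
                rng = np.random.default_rng(seed)
                n = rng.poisson(rate * 200)
                spikes = np.sort(rng.uniform(0, 200, n))
                _, freq = spike_frequency(spikes, window, span=(100, 101), step=1.0)
                centers.append(freq[0])
            var[window] = np.var(centers)
        assert var[10.0] < 0.7 * var[5.0]

    def test_mean_rate(self):
        spikes = np.array([1.0, 2.0, 3.0, 9.0])
        assert mean_rate(spikes, 0.0, 4.0) == pytest.approx(0.75)


class TestSettleTime:
    def test_constant_after_switch_returns_t_off(self):
        t = np.linspace(0, 100, 2001)
        series = np.where(t < 40, 1.0, 2.0)
        assert settle_time(t, series, 40.0) == pytest.approx(40.0, abs=0.1)

    def test_exponential_approach_matches_closed_form(self):
        lam = 0.2
        t = np.linspace(0, 100, 20001)
        plateau = 2.0
        series = np.where(t < 40, 1.0, plateau - (plateau - 1) * np.exp(-lam * (t - 40)))
        # |series - plateau| <= rel_tol * plateau  <=>
        # t - 40 >= -ln(rel_tol * plateau / (plateau - 1)) / lam
        expected = 40.0 + -np.log(0.05 * plateau / (plateau - 1)) / lam
        got = settle_time(t, series, 40.0)
        assert got == pytest.approx(expected, abs=t[1] - t[0] + 1e-9)

    def test_degenerate_tolerance_returns_t_off(self):
        t = np.linspace(0, 100, 2001)
        series = np.where(t < 40, 1.5, 2.0)  # 1.5 within +-100% of 2.0
        assert settle_time(t, series, 40.0, rel_tol=1.0) == pytest.approx(40.0, abs=0.1)

    def test_never_settles_returns_none(self):
        t = np.linspace(0, 100, 2001)
        series = t  # keeps growing
        assert settle_time(t, series, 40.0, rel_tol=0.001) is None

    def test_ensemble_reduces_to_single_trace(self):
        t = np.linspace(0, 100, 2001)
        series = np.where(t < 40, 1.0, 2.0)
        assert ensemble_settle_time(t, [series, series], 40.0) == pytest.approx(
            40.0, abs=0.1
        )


class TestPSnicTrace:
    def test_feedforward_trace_constant(self, params):
        res = integrate(
            params, InputSpec(kind="gaussian", p_bar=85.0, sigma=10.0, seed=2),
            t_span=(0, 3), mode="feedforward", record_stride=10,
        )
        _, trace = p_snic_trace(res, params, stride=20)
        assert np.ptp(trace) == 0.0
        assert trace[0] == pytest.approx(p_snic(0.0, 0.0, params))

    def test_stride_consistency(self, params):
        res = integrate(
            params, InputSpec(kind="constant", p_bar=80.0),
            t_span=(0, 2), record_stride=10,
        )
        t1, tr1 = p_snic_trace(res, params, stride=10)
        t10, tr10 = p_snic_trace(res, params, stride=100)
        shared = np.isin(t1, t10)
        np.testing.assert_array_equal(tr1[shared], tr10)

    def test_post_bolus_trace_decays_toward_baseline(self, params):
        # quiescent feedback run: the bolus raises the threshold, which
        # then relaxes monotonically as GABA is cleared
        out = gaba_bolus_experiment(
            params, InputSpec(kind="constant", p_bar=75.0), amount=20.0,
            t_span=(0, 15), record_stride=10,
        )
        trace = out.p_snic_trace
        assert trace[0] > trace[-1]
        assert np.all(np.diff(trace) < 1e-6)  # monotone decay (tol for fp)
        baseline = p_snic(0.0, 0.0, params)
        assert trace[-1] - baseline < trace[0] - baseline


class TestBolusExperiment:
    def test_null_bolus_identical_to_plain_run(self, params):
        inp = InputSpec(kind="gaussian", p_bar=85.0, sigma=10.0, seed=9)
        a = gaba_bolus_experiment(params, inp, amount=0.0, t_span=(0, 3))
        b = gaba_bolus_experiment(params, inp, amount=0.0, t_span=(0, 3))
        assert np.array_equal(a.result.states, b.result.states)

    def test_feedforward_neural_trajectory_invariant(self, params):
        inp = InputSpec(kind="gaussian", p_bar=85.0, sigma=10.0, seed=4)
        with_b = gaba_bolus_experiment(params, inp, amount=20.0, mode="feedforward",
                                       t_span=(0, 3))
        without = gaba_bolus_experiment(params, inp, amount=0.0, mode="feedforward",
                                        t_span=(0, 3))
        assert np.array_equal(
            with_b.result.states[:, :6], without.result.states[:, :6]
        )

    def test_feedback_bolus_silences_then_releases(self, params):
        p_run = 92.0  # slightly above the coupled baseline threshold
        out = gaba_bolus_experiment(
            params, InputSpec(kind="constant", p_bar=p_run), amount=20.0,
            t_span=(0, 30), record_stride=5,
        )
        above = out.p_snic_trace > p_run
        assert above[0]  # threshold pushed above the drive at injection
        t_release = out.p_snic_t[np.nonzero(above)[0].max()]
        assert 1.0 < t_release < 20.0
        assert np.sum(out.spike_times <= t_release) == 0
        assert np.sum(out.spike_times > t_release) > 5


class TestUptakeDeficiency:
    def test_gaba_knockout_raises_gaba_and_threshold(self, params):
        out = uptake_deficiency_experiment(
            params, "gaba", default_input(params, 1), record_stride=10,
        )
        t = out.result.t
        gaba = out.result["GABA_e"]
        pre = gaba[(t > 20) & (t < 40)].mean()
        post = gaba[t > 80].mean()
        assert post > 1.5 * pre
        ps = out.p_snic_trace
        pt = out.p_snic_t
        assert ps[(pt > 80)].mean() > ps[(pt > 20) & (pt < 40)].mean()

    def test_unknown_kind_rejected(self, params):
        with pytest.raises(ValueError, match="uptake kind"):
            uptake_deficiency_experiment(params, "dopamine", default_input(params, 0))

    def test_feedforward_glial_perturbation_leaves_neurons_untouched(self, params):
        inp = default_input(params, 6)
        pert = uptake_deficiency_experiment(
            params, "gaba", inp, mode="feedforward", t_span=(0, 45), record_stride=10,
        )
        plain = integrate(
            params, inp, t_span=(0, 45), mode="feedforward", record_stride=10,
        )
        assert np.array_equal(pert.result.states[:, :6], plain.states[:, :6])


def test_default_input_tracks_snic_threshold(params):
    spec = default_input(params, seed=3)
    assert spec.sigma == 10.0
    assert spec.p_bar == pytest.approx(p_snic(0.0, 0.0, params) - 5.0)
    assert spec.kind == "gaussian"
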