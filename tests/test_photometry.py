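import numpy as np
import pytest

from gonogo import behavior, choice, photometry, synth
from gonogo.core import PhotometryTrace, Stimulus
from gonogo.synth import SimConfig

from conftest import make_session


def flat_trace(session, value=2.0, rate=200.0):
    dur = session.trials[-1].onset + 6.0
    return PhotometryTrace(0.0, rate, np.full(int(dur * rate), value))


def step_trace(session, onset_latency, amp=1.0, base=2.0, rate=200.0):
    """Baseline `base` with a step of `amp` during each trial's
    [onset_latency, waiting end) window."""
    dur = session.trials[-1].onset + 6.0
    t = np.arange(int(dur * rate)) / rate
    v = np.full(t.size, base)
    for trial in session.trials:
        sel = (t >= trial.onset + onset_latency) & (t < trial.onset + 0.5)
        v[sel] += amp
    return PhotometryTrace(0.0, rate, v)


class TestExtractDff:
    def test_constant_trace_gives_zero(self, nogo_session):
        dff = photometry.extract_dff(flat_trace(nogo_session), nogo_session)
        assert np.allclose(dff.trial_matrix, 0.0)
        assert not dff.bad_trials

    def test_f0_two_f_three_gives_half(self, nogo_session):
        trace = step_trace(nogo_session, 0.0, amp=1.0, base=2.0)
        dff = photometry.extract_dff(trace, nogo_session)
        waiting = (dff.time_axis >= 0.0) & (dff.time_axis < 0.5)
        assert np.allclose(dff.trial_matrix[:, waiting], 0.5)

    def test_gain_invariance(self, nogo_session):
        trace = step_trace(nogo_session, 0.2)
        a = photometry.extract_dff(trace, nogo_session).trial_matrix
        # power-of-two gain: bitwise identical
        exact = PhotometryTrace(trace.t0, trace.rate, 4.0 * trace.values)
        assert np.array_equal(
            a, photometry.extract_dff(exact, nogo_session).trial_matrix)
        # arbitrary gain: identical to rounding error
        close = PhotometryTrace(trace.t0, trace.rate, 3.7 * trace.values)
        b = photometry.extract_dff(close, nogo_session).trial_matrix
        assert np.allclose(a, b, rtol=0, atol=1e-12)

    def test_nonpositive_baseline_recorded_not_raised(self, nogo_session):
        trace = flat_trace(nogo_session, value=0.0)
        dff = photometry.extract_dff(trace, nogo_session)
        assert len(dff.bad_trials) == nogo_session.n_trials
        assert np.all(np.isnan(dff.trial_matrix))

    def test_trace_not_covering_trials_errors(self, nogo_session):
        short = PhotometryTrace(0.0, 200.0, np.ones(100))
        with pytest.raises(ValueError):
            photometry.extract_dff(short, nogo_session)

    def test_noise_only_control_has_no_waiting_response(self, nogo_session):
        """GFP-style control: noise without evoked signal gives a
        waiting-period mean dF/F indistinguishable from zero."""
        cfg = SimConfig(n_trials=60, seed=7, evoked_rate=0.0,
                        phot_noise_sd=0.02)
        trace = synth.generate_photometry(nogo_session, cfg)
        dff = photometry.extract_dff(trace, nogo_session)
        vals = photometry.waiting_mean_response(dff)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se


class TestWaitingMeanResponse:
    def test_step_covering_window_returns_step(self, nogo_session):
        trace = step_trace(nogo_session, 0.0, amp=0.4, base=2.0)
        dff = photometry.extract_dff(trace, nogo_session)
        vals = photometry.waiting_mean_response(dff)
        assert np.allclose(vals, 0.2)

    def test_simulated_fa_gain_gives_positive_choice_pref(self, nogo_session):
        cfg = SimConfig(n_trials=60, seed=8, choice_gain=2.0,
                        phot_noise_sd=0.02)
        trace = synth.generate_photometry(nogo_session, cfg)
        dff = photometry.extract_dff(trace, nogo_session)
        vals = photometry.waiting_mean_response(dff)
        res = choice.unit_choice_result(vals, nogo_session)
        assert res.choice_pref > 0.2


class TestLoessSmooth:
    def test_constant_unchanged(self):
        y = np.full(30, 1.7)
        assert np.allclose(photometry.loess_smooth(y), y)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(40, dtype=float)
        y = 0.3 * x**2 - 2.0 * x + 5.0
        assert np.allclose(photometry.loess_smooth(y, span=7), y, atol=1e-6)

    def test_single_outlier_on_line_suppressed(self):
        x = np.arange(30, dtype=float)
        y = 0.5 * x + 1.0
        y_out = y.copy()
        y_out[14] += 50.0
        smoothed = photometry.loess_smooth(y_out, span=7)
        assert abs(smoothed[14] - y[14]) < 1e-3

    def test_small_span_rejected(self):
        with pytest.raises(ValueError):
            photometry.loess_smooth(np.zeros(20), span=3)


class TestResponseLatency:
    def test_noiseless_step_recovered_within_one_bin(self, nogo_session):
        trace = step_trace(nogo_session, 0.2, amp=0.5)
        dff = photometry.extract_dff(trace, nogo_session)
        res = photometry.response_latency(dff, nogo_session)
        assert res.latency is not None
        assert abs(res.latency - 0.2) <= 0.025

    def test_flat_trace_latency_undefined(self, nogo_session):
        dff = photometry.extract_dff(flat_trace(nogo_session), nogo_session)
        res = photometry.response_latency(dff, nogo_session)
        assert res.latency is None

    def test_answer_period_crossing_reported_separately(self, nogo_session):
        """A response starting after the waiting period is never a
        waiting-period latency."""
        dur = nogo_session.trials[-1].onset + 6.0
        t = np.arange(int(dur * 200)) / 200.0
        v = np.full(t.size, 2.0)
        for trial in nogo_session.trials:
            sel = (t >= trial.onset + 1.0) & (t < trial.onset + 2.0)
            v[sel] += 1.0
        dff = photometry.extract_dff(PhotometryTrace(0.0, 200.0, v), nogo_session)
        res = photometry.response_latency(dff, nogo_session)
        assert res.latency is None
        assert res.answer_crossing is not None and res.answer_crossing >= 0.5

    def test_threshold_is_three_sd_above_baseline(self, nogo_session):
        trace = step_trace(nogo_session, 0.2, amp=0.5)
        dff = photometry.extract_dff(trace, nogo_session)
        res = photometry.response_latency(dff, nogo_session)
        assert res.threshold == pytest.approx(
            res.baseline_mean + 3 * res.baseline_sd)

    def test_shift_equivariance_within_one_bin(self):
        """Shifting the generative onset shifts the latency estimate."""
        lats = []
        for onset in (0.1, 0.3):
            specs = [("NOGO", "OFF", [])] * 30
            s = make_session(specs)
            trace = step_trace(s, onset, amp=0.5)
            dff = photometry.extract_dff(trace, s)
            lats.append(photometry.response_latency(dff, s).latency)
        assert abs((lats[1] - lats[0]) - 0.2) <= 0.025

    def test_monotone_in_generative_onset_latency(self, nogo_session):
        """Estimated latency is non-decreasing in the true onset."""
        est = []
        for onset in (0.1, 0.2, 0.3, 0.4):
            cfg = SimConfig(n_trials=60, seed=9, onset_latency=onset,
                            phot_noise_sd=0.02)
            trace = synth.generate_photometry(nogo_session, cfg)
            dff = photometry.extract_dff(trace, nogo_session)
            res = photometry.response_latency(
                dff, nogo_session,
                predicate=lambda t: t.stimulus is Stimulus.NOGO)
            est.append(res.latency)
        assert all(l is not None for l in est)
        assert np.all(np.diff(est) >= 0)
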