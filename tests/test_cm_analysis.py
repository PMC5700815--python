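"""Capacitance-trace analyses: jumps, slopes, power fits, paired pulses,
replenishment, train segmentation and endocytosis decays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ihcexo as ix
from ihcexo.cm_analysis import CmTrace, fit_line


def _step_trace(jump=20.0, noise=0.0, seed=0, transient=10.0):
    """1 s trace with one 20 ms stimulus at 400 ms and a +jump response.

    A decaying artefact of width ``transient`` ms follows the stimulus."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 1000.0, 1.0)
    cm = np.where(t < 420.0, 0.0, jump).astype(float)
    art = (t >= 420.0) & (t < 420.0 + transient)
    cm[art] += 80.0 * np.exp(-(t[art] - 420.0) / 3.0)
    cm += rng.normal(0.0, noise, t.size)
    return CmTrace(t=t, cm=cm, stim_marks=[(400.0, 420.0)])


class TestDeltaCm:
    def test_flat_trace_zero_jump(self):
        t = np.arange(0.0, 1000.0, 1.0)
        trace = CmTrace(t=t, cm=np.full_like(t, 5.0), stim_marks=[(400.0, 420.0)])
        assert ix.delta_cm(trace) == 0.0

    def test_step_with_transient_recovered(self):
        trace = _step_trace(jump=20.0, noise=0.3, seed=1)
        val = ix.delta_cm(trace, baseline_win=200.0, skip=50.0, response_win=100.0)
        assert val == pytest.approx(20.0, abs=0.5)

    def test_offset_invariance(self):
        a = _step_trace(noise=0.3, seed=2)
        b = CmTrace(t=a.t, cm=a.cm + 1234.5, stim_marks=a.stim_marks)
        assert ix.delta_cm(a) == pytest.approx(ix.delta_cm(b), abs=1e-9)

    def test_two_stimuli_analyzed_independently(self):
        t = np.arange(0.0, 3000.0, 1.0)
        cm = np.zeros_like(t)
        cm[t >= 420.0] += 10.0
        cm[t >= 1920.0] += 7.0
        trace = CmTrace(t=t, cm=cm, stim_marks=[(400.0, 420.0), (1900.0, 1920.0)])
        assert ix.delta_cm(trace, 0) == pytest.approx(10.0)
        assert ix.delta_cm(trace, 1) == pytest.approx(7.0)

    def test_window_overlapping_stimulus_rejected(self):
        t = np.arange(0.0, 3000.0, 1.0)
        trace = CmTrace(t=t, cm=np.zeros_like(t),
                        stim_marks=[(400.0, 420.0), (450.0, 470.0)])
        with pytest.raises(ValueError):
            ix.delta_cm(trace, 0, baseline_win=200.0, skip=10.0, response_win=100.0)


class TestSlopes:
    def test_exact_kinetic_slope_line(self):
        x = np.array([2.0, 5.0, 10.0])
        res = fit_line(x, 0.69 * x)
        assert res.slope == pytest.approx(0.69)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_printed_slope_ratios(self):
        # efficiency, per-Ca-current slopes and kinetic slopes of the two
        # genotypes reproduce the printed fold-changes
        assert round(6.6e-2 / 3.9e-2, 1) == 1.7
        assert round(0.69 / 0.46, 1) == 1.5
        assert round(4.8e-2 / 2.2e-2, 1) == 2.2

    def test_sensitivity_slope_uses_requested_field(self):
        resp = [ix.DepolResponse(dcm=0.048 * i, ica_peak=i) for i in (50, 100, 200, 250)]
        res = ix.sensitivity_slope(resp, x_field="ica")
        assert res.slope == pytest.approx(4.8e-2)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            fit_line(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_ci_coverage_near_95_percent(self):
        """The t-based CI covers the true slope ~95% of the time."""
        rng = np.random.default_rng(7)
        x = np.linspace(1.0, 10.0, 8)
        true = 0.69
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = true * x + rng.normal(0.0, 0.5, x.size)
            res = fit_line(x, y)
            hits += res.ci_low <= true <= res.ci_high
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1, 5, 10)
        y = 2.0 * x + rng.normal(0, 0.1, 10)
        a = fit_line(x, y)
        b = fit_line(10.0 * x, y)
        assert b.slope == pytest.approx(a.slope / 10.0)


class TestPowerFit:
    def test_identity_exponent(self):
        x = np.linspace(1.0, 10.0, 20)
        b, a = ix.power_fit(x, x)
        assert b == pytest.approx(1.0) and a == pytest.approx(1.0)

    @pytest.mark.parametrize("true_b", [0.83, 0.94])
    def test_exponent_recovery_with_noise(self, true_b):
        rng = np.random.default_rng(int(true_b * 100))
        x = np.linspace(20.0, 270.0, 12)
        y = 0.5 * x**true_b * np.exp(rng.normal(0.0, 0.02, x.size))
        b, _ = ix.power_fit(x, y)
        assert b == pytest.approx(true_b, abs=0.05)

    def test_scale_equivariance(self):
        x = np.linspace(1.0, 9.0, 15)
        y = 2.0 * x**0.8
        b1, a1 = ix.power_fit(x, y)
        b2, a2 = ix.power_fit(3.0 * x, y)
        assert b2 == pytest.approx(b1)
        assert a2 == pytest.approx(a1 / 3.0**0.8)

    def test_non_positive_data_rejected(self):
        with pytest.raises(ValueError):
            ix.power_fit(np.array([1.0, -2.0, 3.0]), np.array([1.0, 2.0, 3.0]))


class TestPairedPulse:
    def test_equal_pulses_unity(self):
        assert ix.paired_pulse_ratio(12.0, 12.0) == 1.0

    def test_zero_second_pulse(self):
        assert ix.paired_pulse_ratio(12.0, 0.0) == 0.0

    def test_nonpositive_first_pulse_rejected(self):
        with pytest.raises(ValueError):
            ix.paired_pulse_ratio(0.0, 5.0)

    def test_mutant_ratio_below_control_at_short_ipi(self, control_params,
                                                     mutant_params):
        proto = ix.build_protocol("paired-pulse", ipis=(50.0,))
        _, c1, c2 = ix.synth_paired_pulse(control_params, proto, dt=0.1)
        _, m1, m2 = ix.synth_paired_pulse(mutant_params, proto, dt=0.1)
        assert ix.paired_pulse_ratio(m1[0], m2[0]) < ix.paired_pulse_ratio(c1[0], c2[0])


class TestReplenishment:
    def test_printed_train_rates(self):
        assert ix.replenishment_rate(51.0, 750.0) == pytest.approx(1.51, abs=0.01)
        assert ix.replenishment_rate(189.0, 750.0) == pytest.approx(5.6, abs=0.01)

    def test_zero_release(self):
        assert ix.replenishment_rate(0.0, 750.0) == 0.0

    @given(st.floats(min_value=1, max_value=1e5), st.floats(min_value=1, max_value=1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rate_inverts_conversion(self, n, span):
        assert ix.replenishment_rate(ix.fused_to_cm(n), span) * span == pytest.approx(
            n, rel=1e-12
        )

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            ix.replenishment_rate(51.0, 0.0)


class TestTrainComponents:
    def test_pure_linear_curve_has_no_superlinear_onset(self):
        y = 1.7 * np.arange(1, 51)
        phases = ix.train_components(y)
        assert phases.superlinear_onset is None
        assert phases.linear_slope == pytest.approx(1.7)

    def test_known_linear_slope_recovered_with_noise(self):
        rng = np.random.default_rng(0)
        pulses = np.arange(1, 51)
        y = 12.0 + 1.7 * pulses + rng.normal(0.0, 0.8, 50)
        y[:2] = [8.0, 11.0]  # depletion transient
        phases = ix.train_components(y)
        assert phases.linear_slope == pytest.approx(1.7, abs=0.1)

    def test_model_control_curve_onset_in_late_third(self, control_train_curve):
        phases = ix.train_components(control_train_curve)
        assert phases.superlinear_onset is not None
        assert 23 <= phases.superlinear_onset <= 40

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ValueError):
            ix.train_components(np.arange(5, dtype=float))


class TestEndocytosis:
    def test_linear_decay_rate_recovery(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 16_000.0, 10.0)
        cm = np.where(t < 1000.0, 100.0, 100.0 - 6.4 * (t - 1000.0) / 1000.0)
        trace = CmTrace(t=t, cm=cm + rng.normal(0, 1.0, t.size),
                        stim_marks=[(900.0, 1000.0)])
        res = ix.endocytosis_fit(trace, mode="linear", skip=0.0)
        assert res.mode == "linear"
        assert res.linear_rate == pytest.approx(6.4, abs=0.5)

    def test_exponential_component_recovery(self):
        rng = np.random.default_rng(6)
        t = np.arange(0.0, 21_000.0, 10.0)
        ts = np.clip((t - 1000.0) / 1000.0, 0.0, None)
        cm = 266.0 * np.exp(-ts / 3.2) + 40.0 - 2.0 * ts
        trace = CmTrace(t=t, cm=cm + rng.normal(0, 2.0, t.size),
                        stim_marks=[(500.0, 1000.0)])
        res = ix.endocytosis_fit(trace, mode="exp-plus-linear", skip=0.0)
        assert res.tau == pytest.approx(3.2, rel=0.1)
        assert res.amplitude == pytest.approx(266.0, rel=0.1)
        assert res.linear_rate == pytest.approx(2.0, rel=0.2)

    def test_flat_trace_zero_rate(self):
        t = np.arange(0.0, 8000.0, 10.0)
        trace = CmTrace(t=t, cm=np.full_like(t, 50.0), stim_marks=[(100.0, 200.0)])
        res = ix.endocytosis_fit(trace, mode="linear")
        assert res.linear_rate == pytest.approx(0.0, abs=1e-9)

    def test_short_segment_rejected(self):
        t = np.arange(0.0, 3000.0, 10.0)
        trace = CmTrace(t=t, cm=np.zeros_like(t), stim_marks=[(100.0, 200.0)])
        with pytest.raises(ValueError):
            ix.endocytosis_fit(trace, mode="linear")
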