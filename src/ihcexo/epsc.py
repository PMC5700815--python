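"""Detection and quantification of excitatory postsynaptic currents.

EPSCs recorded at the afferent bouton are inward (negative) deflections
riding on Gaussian baseline noise.  Events are detected against a robust
(MAD-based) noise estimate from the pre-stimulus baseline; amplitudes of
overlapping events are corrected by fitting the decay of the preceding
event and subtracting its extrapolated value at the later peak; decay time
constants are fitted on monophasic events only.  A Poisson-train generator
with a difference-of-exponentials kernel provides ground-truthed synthetic
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats


@dataclass
class EPSCTrain:
    """Postsynaptic current (pA, inward negative) with the stimulus onset."""

    t: np.ndarray               # ms
    i: np.ndarray               # pA
    stim_onset: float           # ms

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.i = np.asarray(self.i, float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("t and i must be 1-D arrays of equal length")
        d = np.diff(self.t)
        if np.max(np.abs(d - d[0])) > 1e-6 * d[0]:
            raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("non-finite current values")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class EPSCEvent:
    peak_time: float            # ms
    amplitude: float            # pA, positive magnitude
    tau: float = np.nan         # ms
    monophasic: bool = True
    overlap_corrected: bool = False
    correction_failed: bool = False

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


def baseline_noise(train: EPSCTrain) -> tuple[float, float]:
    """(median, robust sd) of the pre-stimulus baseline (MAD * 1.4826)."""
    base = train.i[train.t < train.stim_onset]
    if base.size == 0 or train.stim_onset - train.t[0] < 1000.0:
        raise ValueError("need >= 1 s of baseline before stim_onset")
    med = float(np.median(base))
    sd = float(stats.median_abs_deviation(base, scale="normal"))
    return med, sd


def detect_events(
    train: EPSCTrain,
    threshold_k: float = 5.0,
    refractory: float = 1.0,
    smooth_ms: float = 0.3,
) -> list[EPSCEvent]:
    """Threshold-crossing event detection on the inverted trace.

    The trace is lightly boxcar-smoothed (``smooth_ms``; picking the raw
    noisy maximum would bias amplitudes upward), then peaks of
    -(i - baseline) exceeding ``threshold_k`` times the MAD noise in both
    height and prominence are events (the prominence requirement rejects
    noise maxima riding on an event's decay); peaks closer than
    ``refractory`` ms are merged (largest kept).  Amplitudes are peak
    deflections from the baseline median.
    """
    med, _ = baseline_noise(train)
    y = -(train.i - med)
    w = max(int(round(smooth_ms / train.dt)), 1)
    if w > 1:
        if w % 2 == 0:
            w += 1
        y = np.convolve(np.pad(y, w // 2, mode="edge"), np.ones(w) / w, mode="valid")
    base = y[train.t < train.stim_onset]
    sd = float(stats.median_abs_deviation(base, scale="normal"))
    min_dist = max(int(round(refractory / train.dt)), 1)
    peaks, props = signal.find_peaks(
        y, height=threshold_k * sd, prominence=threshold_k * sd, distance=min_dist
    )
    return [
        EPSCEvent(peak_time=float(train.t[p]), amplitude=float(y[p]))
        for p in peaks
    ]


def _fit_decay(t, y, tau0):
    """Monoexponential decay fit y = A*exp(-t/tau); t relative to peak."""
    popt, _ = optimize.curve_fit(
        lambda tt, A, tau: A * np.exp(-tt / tau),
        t, y, p0=(max(float(y[0]), 1e-6), tau0),
        bounds=([1e-9, 1e-3], [np.inf, np.inf]), maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def overlap_corrected_amplitude(
    train: EPSCTrain,
    events: list[EPSCEvent],
    overlap_factor: float = 5.0,
    tau_guess: float = 1.0,
) -> list[EPSCEvent]:
    """Correct amplitudes of events riding on the decay of the previous one.

    For an event starting within ``overlap_factor`` x tau of the previous
    peak, the previous decay is fitted with a monoexponential and its
    extrapolated value at the later peak is subtracted.  Events are
    returned in time order with flags set; a failed decay fit leaves the
    amplitude uncorrected and flags it.
    """
    events = sorted(events, key=lambda e: e.peak_time)
    if len(events) < 2:
        return events
    med, _ = baseline_noise(train)
    y = -(train.i - med)
    out = [events[0]]
    for prev, ev in zip(events, events[1:]):
        gap = ev.peak_time - prev.peak_time
        tau_ref = prev.tau if np.isfinite(prev.tau) else tau_guess
        if gap > overlap_factor * tau_ref:
            out.append(ev)
            continue
        # fit the previous event's decay only down to the inter-peak valley,
        # which marks the onset of the rising phase of the present event
        sel = (train.t > prev.peak_time) & (train.t < ev.peak_time - 2 * train.dt)
        tt = train.t[sel] - prev.peak_time
        yy = y[sel]
        if tt.size >= 4:
            valley = int(np.argmin(yy))
            if valley >= 4:
                tt, yy = tt[:valley], yy[:valley]
        if tt.size < 4:
            out.append(
                EPSCEvent(ev.peak_time, ev.amplitude, ev.tau, ev.monophasic,
                          overlap_corrected=False, correction_failed=True)
            )
            continue
        try:
            A, tau = _fit_decay(tt, yy, tau_ref)
        except RuntimeError:
            out.append(
                EPSCEvent(ev.peak_time, ev.amplitude, ev.tau, ev.monophasic,
                          overlap_corrected=False, correction_failed=True)
            )
            continue
        resid = A * np.exp(-gap / tau)
        corrected = ev.amplitude - resid
        if corrected <= 0:
            out.append(
                EPSCEvent(ev.peak_time, ev.amplitude, ev.tau, ev.monophasic,
                          overlap_corrected=False, correction_failed=True)
            )
            continue
        out.append(
            EPSCEvent(ev.peak_time, corrected, tau, monophasic=False,
                      overlap_corrected=True)
        )
    return out


def decay_tau(train: EPSCTrain, event: EPSCEvent, return_frac: float = 0.05) -> float:
    """Decay time constant (ms) of a monophasic EPSC.

    Fits a monoexponential from the peak until the current first returns
    to ``return_frac`` of the peak (or the end of the trace).  Refuses
    non-monophasic events, matching the convention of computing taus from
    monophasic EPSCs only.
    """
    if not event.monophasic:
        raise ValueError("decay_tau is defined for monophasic events only")
    med, _ = baseline_noise(train)
    y = -(train.i - med)
    i0 = int(np.searchsorted(train.t, event.peak_time))
    below = np.nonzero(y[i0:] < return_frac * event.amplitude)[0]
    i1 = i0 + int(below[0]) if below.size else y.size
    if i1 - i0 < 4:
        raise RuntimeError("decay segment too short to fit")
    tt = train.t[i0:i1] - train.t[i0]
    _, tau = _fit_decay(tt, y[i0:i1], tau0=1.0)
    return tau


def rate_first_10s(events: list[EPSCEvent], stim_onset: float, recording_end: float) -> float:
    """Mean event rate (events/s) in the first 10 s after the stimulus."""
    if recording_end - stim_onset < 10_000.0:
        raise ValueError("recording must extend >= 10 s past stim_onset")
    n = sum(1 for e in events if stim_onset < e.peak_time <= stim_onset + 10_000.0)
    return n / 10.0


def amplitude_cdf_compare(a, b):
    """Two-sample KS comparison of EPSC amplitude distributions.

    Returns (KS statistic, p value); requires >= 10 events per sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 events per sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def synth_epsc_train(
    rate: float = 20.0,
    amp_mean: float = 250.0,
    amp_sigma: float = 0.3,
    tau_rise: float = 0.2,
    tau_decay: float = 1.0,
    noise_sd: float = 5.0,
    duration: float = 15_000.0,
    baseline: float = 2000.0,
    dt: float = 0.1,
    seed: int = 0,
    rate_profile=None,
):
    """Ground-truthed synthetic EPSC recording.

    Events are a (possibly inhomogeneous) Poisson process after
    ``baseline`` ms, with lognormal amplitudes (median ``amp_mean`` pA,
    log-sd ``amp_sigma``) and a peak-normalized difference-of-exponentials
    kernel; Gaussian noise is added.  ``rate_profile(t_ms)`` overrides the
    constant rate (events/s) via thinning.

    Returns (EPSCTrain, list of ground-truth (time, amplitude) pairs).
    """
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    i = rng.normal(0.0, noise_sd, size=n)
    # peak-normalized kernel
    tp = (np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise))
    kern_t = np.arange(0.0, 10 * tau_decay, dt)
    kern = np.exp(-kern_t / tau_decay) - np.exp(-kern_t / tau_rise)
    kern /= np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    rmax = rate if rate_profile is None else max(
        float(np.max([rate_profile(x) for x in np.linspace(baseline, duration, 200)])), 1e-9
    )
    truth = []
    tev = baseline
    while True:
        tev += rng.exponential(1000.0 / rmax)  # ms
        if tev >= duration - 10 * tau_decay:
            break
        if rate_profile is not None and rng.uniform() > rate_profile(tev) / rmax:
            continue
        amp = rng.lognormal(np.log(amp_mean), amp_sigma)
        onset = int(round((tev - tp) / dt))  # peak lands at tev
        seg = slice(max(onset, 0), min(onset + kern.size, n))
        i[seg] -= amp * kern[: seg.stop - seg.start]
        truth.append((tev, amp))
    train = EPSCTrain(t=t, i=i, stim_onset=baseline)
    return train, truth
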