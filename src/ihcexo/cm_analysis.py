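"""Membrane-capacitance trace analysis.

Whole-cell capacitance (C_m) jumps report net exocytosis: each fused
vesicle adds ~45 aF of membrane.  This module implements the standard
measurements made on C_m recordings from hair cells: baseline-corrected
capacitance jumps, Ca2+-efficiency and kinetic slopes, power-law fits,
paired-pulse ratios, replenishment rates, three-phase segmentation of
cumulative release during pulse trains, and endocytosis decay fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import cm_to_vesicles


@dataclass
class CmTrace:
    """Capacitance time series (t in ms, cm in fF) with stimulus windows."""

    t: np.ndarray
    cm: np.ndarray
    stim_marks: list = field(default_factory=list)  # [(start_ms, end_ms), ...]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.cm = np.asarray(self.cm, float)
        if self.t.shape != self.cm.shape or self.t.ndim != 1:
            raise ValueError("t and cm must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        marks = sorted((float(a), float(b)) for a, b in self.stim_marks)
        for (a, b) in marks:
            if not (self.t[0] <= a <= b <= self.t[-1]):
                raise ValueError("stimulus window outside the trace")
        for (_, b0), (a1, _) in zip(marks, marks[1:]):
            if a1 < b0:
                raise ValueError("stimulus windows overlap")
        self.stim_marks = marks

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass
class DepolResponse:
    """One depolarization: capacitance jump and its stimulus descriptors."""

    dcm: float                  # fF
    ica_peak: float = np.nan    # pA (magnitude)
    q: float = np.nan           # integrated Ca2+ charge, C
    step_v: float = np.nan      # mV
    step_dur: float = np.nan    # ms


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope + 1e-12 and self.slope - 1e-12 <= self.ci_high):
            raise ValueError("confidence interval must bracket the slope")


@dataclass
class EndoFit:
    """Endocytosis decay fit; rates/amplitudes are positive declines."""

    mode: str                   # "linear" | "exp-plus-linear"
    linear_rate: float          # fF/s
    tau: float = np.nan         # s
    amplitude: float = np.nan   # fF


@dataclass
class TrainPhases:
    """Three-phase segmentation of cumulative release during a train."""

    depletion_end: int          # last pulse (1-based) of the depletion phase
    linear_slope: float         # fF per depolarization step
    superlinear_onset: int | None  # first superlinear pulse (1-based), or None


def delta_cm(
    trace: CmTrace,
    stim_index: int = 0,
    baseline_win: float = 200.0,
    skip: float = 50.0,
    response_win: float = 100.0,
) -> float:
    """Capacitance jump for one stimulus: mean(response) - mean(baseline).

    The baseline is averaged over ``baseline_win`` ms ending at stimulus
    onset; the response over ``response_win`` ms starting ``skip`` ms after
    stimulus end (skipping the transient-current artefact).  Both windows
    must be clear of every stimulus.
    """
    s, e = trace.stim_marks[stim_index]
    b0, b1 = s - baseline_win, s
    r0, r1 = e + skip, e + skip + response_win
    if b0 < trace.t[0] or r1 > trace.t[-1]:
        raise ValueError("analysis windows fall outside the trace")
    for (a, b) in trace.stim_marks:
        if (b0 < b and a < b1) or (r0 < b and a < r1):
            raise ValueError("analysis window overlaps a stimulus")
    base = trace.cm[(trace.t >= b0) & (trace.t < b1)]
    resp = trace.cm[(trace.t >= r0) & (trace.t <= r1)]
    if base.size == 0 or resp.size == 0:
        raise ValueError("empty analysis window")
    return float(resp.mean() - base.mean())


def fit_line(x, y, conf: float = 0.95) -> SlopeFit:
    """Ordinary least-squares line with a t-based CI on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa (all x equal)")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + conf / 2, x.size - 2)
    half = tcrit * res.stderr
    return SlopeFit(res.slope, res.intercept, res.slope - half, res.slope + half)


def sensitivity_slope(responses, x_field: str = "ica") -> SlopeFit:
    """Linear Ca2+-efficiency (dC_m vs I_Ca or charge) or kinetic (vs
    duration) slope, with a 95% CI from the slope's standard error."""
    getters = {"ica": "ica_peak", "q": "q", "step_dur": "step_dur"}
    if x_field not in getters:
        raise ValueError(f"x_field must be one of {sorted(getters)}")
    x = np.array([getattr(r, getters[x_field]) for r in responses], float)
    y = np.array([r.dcm for r in responses], float)
    return fit_line(x, y)


def power_fit(x, y=None):
    """Least-squares fit of y = a * x**b in log-log space.

    Accepts either (x, y) arrays or a list of DepolResponse (x = charge,
    y = dcm).  Returns (exponent b, scale a).
    """
    if y is None:
        resp = list(x)
        x = np.array([r.q for r in resp], float)
        y = np.array([r.dcm for r in resp], float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit needs strictly positive data")
    b, loga = np.polyfit(np.log(x), np.log(y), 1)
    return float(b), float(np.exp(loga))


def paired_pulse_ratio(dcm1: float, dcm2: float) -> float:
    """Replenishment index dC2/dC1 for two identical depolarizations."""
    if dcm1 <= 0:
        raise ValueError("first-pulse response must be > 0")
    return float(dcm2) / float(dcm1)


def paired_pulse_series(dcm1, dcm2):
    """Vector of paired-pulse ratios over a series of interpulse intervals."""
    return np.array([paired_pulse_ratio(a, b) for a, b in zip(dcm1, dcm2)])


def replenishment_rate(total_dcm: float, span: float) -> float:
    """Sustained vesicle supply rate, vesicles/ms, from a total capacitance
    gain (fF) over a stimulation span (ms; by default the full train span,
    depolarized plus interpulse time)."""
    if span <= 0:
        raise ValueError("span must be > 0")
    if total_dcm < 0:
        raise ValueError("total_dcm must be >= 0")
    return cm_to_vesicles(total_dcm) / span


def train_components(
    cumulative,
    depletion_end: int = 3,
    linear_end: int = 23,
    detect_factor: float = 2.0,
    min_run: int = 3,
) -> TrainPhases:
    """Segment a cumulative-release curve from a pulse train into the
    classical three phases: rapid pool depletion, linear replenishment-
    limited release, and an optional late superlinear phase.

    The linear slope is fitted (OLS) on pulses ``depletion_end..linear_end``.
    Superlinear onset is the first pulse where the centered 3-point
    per-step increment exceeds ``detect_factor`` times the linear slope for
    at least ``min_run`` consecutive pulses.
    """
    if hasattr(cumulative, "x") and hasattr(cumulative, "sd"):
        cumulative = cumulative.mean  # ObservedCmCurve
    y = np.asarray(cumulative, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 pulses")
    lin_hi = min(linear_end, n)
    pulses = np.arange(1, n + 1)
    sel = (pulses >= depletion_end) & (pulses <= lin_hi)
    slope = float(stats.linregress(pulses[sel], y[sel]).slope)
    # centered per-step increments, pulses 2..n-1
    inc = (y[2:] - y[:-2]) / 2.0
    above = inc > detect_factor * max(slope, 1e-12)
    onset = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run:
            onset = i - min_run + 1 + 2  # back to 1-based pulse index
            break
    if onset is not None and onset <= depletion_end:
        onset = None  # early depletion transient, not late recruitment
    return TrainPhases(depletion_end, slope, onset)


def endocytosis_fit(
    trace: CmTrace,
    mode: str = "linear",
    skip: float = 100.0,
) -> EndoFit:
    """Fit the post-stimulus C_m decline (membrane retrieval).

    ``linear`` fits a straight line and reports the decline rate in fF/s.
    ``exp-plus-linear`` fits A*exp(-t/tau) + b*t + c and reports the
    exponential amplitude A (fF), time constant tau (s) and the linear
    decline rate -b (fF/s).  The decay segment starts ``skip`` ms after the
    last stimulus and must span at least 5 s.
    """
    if not trace.stim_marks:
        t0 = trace.t[0]
    else:
        t0 = trace.stim_marks[-1][1] + skip
    sel = trace.t >= t0
    t_s = (trace.t[sel] - t0) / 1000.0
    y = trace.cm[sel]
    if t_s.size < 10 or t_s[-1] < 5.0:
        raise ValueError("decay segment must span at least 5 s")
    if mode == "linear":
        slope, _ = np.polyfit(t_s, y, 1)
        return EndoFit(mode="linear", linear_rate=float(-slope))
    if mode == "exp-plus-linear":
        def f(t, A, tau, b, c):
            return A * np.exp(-t / tau) + b * t + c

        amp0 = max(float(y[0] - y[-1]), 1.0)
        p0 = (amp0, max(t_s[-1] / 4.0, 0.5), 0.0, float(y[-1]))
        try:
            popt, _ = optimize.curve_fit(
                f, t_s, y, p0=p0,
                bounds=([0, 1e-3, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:
            raise RuntimeError(f"exponential decay fit did not converge: {err}")
        A, tau, b, _ = popt
        return EndoFit(
            mode="exp-plus-linear",
            linear_rate=float(-b),
            tau=float(tau),
            amplitude=float(A),
        )
    raise ValueError("mode must be 'linear' or 'exp-plus-linear'")
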