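"""Synthetic stimulus protocols, Ca2+ currents, charge drives and noisy
capacitance observations.

This module stands in for the raw patch-clamp recordings: it builds the
standard depolarization protocols (single step, duration series,
paired pulse, 50-pulse train), synthesizes leak-subtracted Ca2+ current
traces with a Boltzmann-activation x linear-driving-force I-V shape,
integrates them into cumulative-charge drives, and produces noisy
capacitance curves by running the four-pool model forward.  All
generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PoolParams, CalciumDrive, simulate
from .cm_analysis import CmTrace
from .calcium import FluorescenceTrace, HillParams, hill_curve, ogb5n_fluorescence

#: pA * ms -> coulombs
_PA_MS_TO_C = 1e-15

PROTOCOL_KINDS = ("single-step", "duration-series", "paired-pulse", "train")


@dataclass
class IVParams:
    """Boltzmann x driving-force parametrization of the Ca2+ current.

    i(V) = gmax * (V - vrev) / (1 + exp(-(V - vhalf)/kslope)), giving the
    typical inverted bell I-V with a negative peak near -10 mV for the
    defaults.  Plumbing for the generators; not a channel-gating model.
    """

    gmax: float = 1.0       # pA/mV
    vrev: float = 45.0      # mV
    vhalf: float = -25.0    # mV
    kslope: float = 7.0     # mV
    noise_sd: float = 5.0   # pA

    def __post_init__(self) -> None:
        if self.kslope <= 0:
            raise ValueError("kslope must be > 0")
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")

    def current(self, v):
        v = np.asarray(v, float)
        out = self.gmax * (v - self.vrev) / (1.0 + np.exp(-(v - self.vhalf) / self.kslope))
        return float(out) if out.ndim == 0 else out


@dataclass
class CurrentTrace:
    """Leak-subtracted Ca2+ current (pA, inward negative) vs time (ms)."""

    t: np.ndarray
    i: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.i = np.asarray(self.i, float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("t and i must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite time values")

    @property
    def peak(self) -> float:
        """Peak inward amplitude, pA (positive magnitude)."""
        return float(-np.min(self.i))


@dataclass
class ObservedCmCurve:
    """Observed (noisy) dC_m curve: x is pulse index, step duration (ms) or
    step voltage (mV); mean and per-point sd in fF."""

    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        if not (self.x.shape == self.mean.shape == self.sd.shape):
            raise ValueError("x, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")


@dataclass
class StimulusProtocol:
    """Voltage protocol made of holding/test segments.

    Defaults follow the standard hair-cell protocols: holding -95 mV, test
    -10 mV; duration series 2..50 ms; paired 20-ms pulses with interpulse
    intervals 50..1000 ms; train of 50 x 5 ms pulses, 10 ms apart.
    Multi-sweep kinds (duration-series, paired-pulse) expose one sweep per
    series value.
    """

    kind: str
    holding_mv: float = -95.0
    test_mv: float = -10.0
    pre_ms: float = 100.0
    post_ms: float = 200.0
    step_ms: float = 20.0                                    # single-step
    durations: tuple = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 50.0)  # duration-series
    ipis: tuple = (50.0, 100.0, 200.0, 500.0, 1000.0)        # paired-pulse
    pp_pulse_ms: float = 20.0                                # paired-pulse
    n_pulses: int = 50                                       # train
    pulse_ms: float = 5.0                                    # train
    ipi_ms: float = 10.0                                     # train

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        for name in ("pre_ms", "post_ms", "step_ms", "pp_pulse_ms", "pulse_ms", "ipi_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_sweeps(self) -> int:
        if self.kind == "duration-series":
            return len(self.durations)
        if self.kind == "paired-pulse":
            return len(self.ipis)
        return 1

    @property
    def train_span_ms(self) -> float:
        """Full span of the train, depolarized plus interpulse time."""
        return self.n_pulses * (self.pulse_ms + self.ipi_ms)

    def segments(self, sweep: int = 0) -> list:
        """(voltage mV, duration ms) list for one sweep."""
        h, v = self.holding_mv, self.test_mv
        if self.kind == "single-step":
            return [(h, self.pre_ms), (v, self.step_ms), (h, self.post_ms)]
        if self.kind == "duration-series":
            return [(h, self.pre_ms), (v, self.durations[sweep]), (h, self.post_ms)]
        if self.kind == "paired-pulse":
            ipi = self.ipis[sweep]
            return [
                (h, self.pre_ms),
                (v, self.pp_pulse_ms),
                (h, ipi),
                (v, self.pp_pulse_ms),
                (h, self.post_ms),
            ]
        segs = [(h, self.pre_ms)]
        for _ in range(self.n_pulses):
            segs.append((v, self.pulse_ms))
            segs.append((h, self.ipi_ms))
        segs.append((h, self.post_ms))
        return segs

    def stim_windows(self, sweep: int = 0) -> list:
        """(start, end) ms of every test-potential segment of a sweep."""
        out, t = [], 0.0
        for v, dur in self.segments(sweep):
            if v != self.holding_mv:
                out.append((t, t + dur))
            t += dur
        return out

    def sweep_span(self, sweep: int = 0) -> float:
        return float(sum(d for _, d in self.segments(sweep)))

    def sample_times(self, sweep: int = 0, response_delay: float = 50.0) -> np.ndarray:
        """Times at which the cumulative dC_m curve is read out.

        Trains are sampled at the end of every interpulse interval; step
        protocols ``response_delay`` ms after the (last) step ends.
        """
        if self.kind == "train":
            period = self.pulse_ms + self.ipi_ms
            return self.pre_ms + period * np.arange(1, self.n_pulses + 1)
        end = self.stim_windows(sweep)[-1][1]
        return np.array([end + response_delay])

    def x_values(self) -> np.ndarray:
        if self.kind == "train":
            return np.arange(1, self.n_pulses + 1, dtype=float)
        if self.kind == "duration-series":
            return np.asarray(self.durations, float)
        if self.kind == "paired-pulse":
            return np.asarray(self.ipis, float)
        return np.array([self.step_ms])


def build_protocol(kind: str, **overrides) -> StimulusProtocol:
    """Build one of the standard protocols; keyword overrides accepted."""
    return StimulusProtocol(kind=kind, **overrides)


def synth_ica(
    protocol: StimulusProtocol,
    iv: IVParams | None = None,
    seed: int | None = 0,
    dt: float = 0.05,
    sweep: int = 0,
) -> CurrentTrace:
    """Synthesize a leak-subtracted Ca2+ current trace for one sweep.

    The current is the I-V value at the test potential during each
    depolarized segment and zero at holding; Gaussian noise of
    ``iv.noise_sd`` pA is added everywhere (omitted when seed is None).
    """
    iv = iv or IVParams()
    span = protocol.sweep_span(sweep)
    n = int(round(span / dt)) + 1
    t = dt * np.arange(n)
    i = np.zeros(n)
    cursor = 0.0
    for v, dur in protocol.segments(sweep):
        if v != protocol.holding_mv:
            sel = (t >= cursor) & (t < cursor + dur)
            i[sel] = iv.current(v)
        cursor += dur
    if seed is not None and iv.noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, iv.noise_sd, size=n)
    return CurrentTrace(t=t, i=i)


def integrate_charge(trace: CurrentTrace) -> CalciumDrive:
    """Cumulative charge drive from a current trace (Ca2+ charge proxy).

    Integrates the rectified current |i| by the trapezoid rule; the inward
    current is negative by convention, so rectification keeps the drive
    non-decreasing.  Output charge is in coulombs (pA*ms = 1e-15 C).
    """
    if not np.all(np.isfinite(trace.i)):
        raise ValueError("current trace contains NaN/inf")
    absi = np.abs(trace.i)
    dt = np.diff(trace.t)
    inc = 0.5 * (absi[1:] + absi[:-1]) * dt * _PA_MS_TO_C
    q = np.concatenate([[0.0], np.cumsum(inc)])
    return CalciumDrive(t=trace.t.copy(), q=q)


def make_drive(
    protocol: StimulusProtocol,
    iv: IVParams | None = None,
    dt: float = 0.05,
    sweep: int = 0,
) -> CalciumDrive:
    """Noise-free cumulative-charge drive for one sweep of a protocol."""
    trace = synth_ica(protocol, iv, seed=None, dt=dt, sweep=sweep)
    return integrate_charge(trace)


def model_cm_curve(
    params: PoolParams,
    protocol: StimulusProtocol,
    drives,
    dt: float = 0.05,
    response_delay: float = 50.0,
) -> np.ndarray:
    """Noise-free model prediction of the observed cumulative dC_m curve.

    ``drives`` is a CalciumDrive (single-sweep protocols) or one drive per
    sweep.  Returns the model dC_m (fF) at the protocol's sample times,
    matching ``x_values`` in length.
    """
    if isinstance(drives, CalciumDrive):
        drives = [drives] * protocol.n_sweeps
    if len(drives) != protocol.n_sweeps:
        raise ValueError("need one drive per sweep")
    out = []
    for sweep in range(protocol.n_sweeps):
        ts = protocol.sample_times(sweep, response_delay)
        traj = simulate(params, drives[sweep], dt=dt, t_end=float(ts[-1]))
        out.append(np.interp(ts, traj.t, traj.cm))
    return np.concatenate(out)


def synth_cm_observation(
    params: PoolParams,
    protocol: StimulusProtocol,
    iv: IVParams | None = None,
    noise_sd: float | np.ndarray = 2.0,
    seed: int = 0,
    dt: float = 0.05,
    response_delay: float = 50.0,
) -> ObservedCmCurve:
    """Noisy observed dC_m curve from the forward model.

    Simulates the model over each sweep (noise-free drive), samples the
    cumulative dC_m at the protocol's sample times and adds i.i.d.
    Gaussian noise (scalar or per-point sd, fF).
    """
    if protocol.kind == "paired-pulse":
        raise ValueError("use synth_paired_pulse for paired-pulse protocols")
    # drive grid fixed at 0.05 ms so the drive is independent of the sim step
    drives = [
        make_drive(protocol, iv, dt=min(dt, 0.05), sweep=s)
        for s in range(protocol.n_sweeps)
    ]
    mean = model_cm_curve(params, protocol, drives, dt=dt, response_delay=response_delay)
    sd = np.broadcast_to(np.asarray(noise_sd, float), mean.shape).copy()
    rng = np.random.default_rng(seed)
    noisy = mean + rng.normal(0.0, 1.0, size=mean.shape) * sd
    return ObservedCmCurve(x=protocol.x_values(), mean=noisy, sd=sd)


def synth_paired_pulse(
    params: PoolParams,
    protocol: StimulusProtocol,
    iv: IVParams | None = None,
    dt: float = 0.05,
    response_delay: float = 20.0,
):
    """Model paired-pulse responses: (ipis, dcm1, dcm2) arrays in fF.

    dcm1 is the cumulative release at the end of the interpulse interval;
    dcm2 the additional release from the second pulse (read out
    ``response_delay`` ms after it ends).
    """
    if protocol.kind != "paired-pulse":
        raise ValueError("protocol must be paired-pulse")
    dcm1, dcm2 = [], []
    for sweep in range(protocol.n_sweeps):
        drive = make_drive(protocol, iv, dt=min(dt, 0.05), sweep=sweep)
        (s1, e1), (s2, e2) = protocol.stim_windows(sweep)
        t_end = min(e2 + response_delay, float(drive.t[-1]))
        traj = simulate(params, drive, dt=dt, t_end=t_end)
        c1 = float(np.interp(s2, traj.t, traj.cm))
        c2 = float(np.interp(t_end, traj.t, traj.cm))
        dcm1.append(c1)
        dcm2.append(c2 - c1)
    return np.asarray(protocol.ipis, float), np.array(dcm1), np.array(dcm2)


def synth_uncaging(
    ca_peak: float = 59.0,
    rise_tau: float = 28.8 / np.log(9.0),
    hill: HillParams | None = None,
    total_cm: float = 2250.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    vmax_rate: float = 25.0,
    flash_t: float = 50.0,
    duration: float = 600.0,
    dt: float = 1.0,
    fmin: float = 10.0,
    fmax: float = 200.0,
):
    """Synthetic Ca2+-uncaging experiment: paired fluorescence and C_m traces.

    After the flash, [Ca2+] rises exponentially to ``ca_peak`` µM with time
    constant ``rise_tau`` ms (default gives a 10-90% rise time of 28.8 ms).
    Release follows dC_m/dt = vmax_rate * Hill([Ca2+]) * (1 - C_m/total_cm),
    so cumulative release saturates toward ``total_cm``.  The fluorescence
    trace is the inverse OGB-5N calibration of the [Ca2+] time course.
    """
    if ca_peak <= 0:
        raise ValueError("ca_peak must be > 0")
    hill = hill or HillParams(vmax=1.0, n=3.3, ec50=2.3)
    if hill.ec50 <= 0:
        raise ValueError("EC50 must be > 0")
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    ca = np.where(t < flash_t, 0.0, ca_peak * (1.0 - np.exp(-(t - flash_t) / rise_tau)))
    # integrate release on a 10x finer grid (forward Euler is adequate there)
    sub = 10
    tf = np.linspace(t[0], t[-1], (n - 1) * sub + 1)
    caf = np.where(tf < flash_t, 0.0, ca_peak * (1.0 - np.exp(-(tf - flash_t) / rise_tau)))
    hf = hill_curve(caf, 1.0, hill.n, hill.ec50)
    cm = np.empty_like(tf)
    cm[0] = 0.0
    h = tf[1] - tf[0]
    for i in range(tf.size - 1):
        cm[i + 1] = cm[i] + h * vmax_rate * hf[i] * max(1.0 - cm[i] / total_cm, 0.0)
    cm = cm[::sub]
    rng = np.random.default_rng(seed)
    cm_noisy = cm + rng.normal(0.0, noise_sd, size=n)
    f = ogb5n_fluorescence(ca, fmin, fmax)
    fluo = FluorescenceTrace(t=t, f=f, fmin=fmin, fmax=fmax)
    trace = CmTrace(t=t, cm=cm_noisy, stim_marks=[(flash_t, flash_t)])
    return fluo, trace
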