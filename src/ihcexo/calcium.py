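"""Fluorescence-based Ca2+ quantification and Ca2+-dependence of release.

Covers calibration of the low-affinity indicator OGB-5N
([Ca2+] = K_D (F - Fmin)/(Fmax - F)), release-rate traces (dC_m/dt),
Hill fits of rate vs [Ca2+] with a half-max fallback when the data do not
reach plateau, and the kinetic metrics of flash-photolysis (Ca2+ uncaging)
responses: onset delay, time to peak release rate, and peak rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cm_analysis import CmTrace

#: in-situ dissociation constant of OGB-5N in hair-cell cytoplasm, µM
OGB5N_KD_UM = 23.30


@dataclass
class FluorescenceTrace:
    """Raw indicator fluorescence with its calibration anchors."""

    t: np.ndarray
    f: np.ndarray
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.f = np.asarray(self.f, float)
        if self.fmin >= self.fmax:
            raise ValueError("fmin must be < fmax")

    def calcium(self, kd: float = OGB5N_KD_UM) -> np.ndarray:
        return ogb5n_calibrate(self.f, self.fmin, self.fmax, kd)


@dataclass
class HillParams:
    """Hill model y = vmax * x^n / (ec50^n + x^n)."""

    vmax: float
    n: float
    ec50: float
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")

    def __call__(self, x):
        return hill_curve(np.asarray(x, float), self.vmax, self.n, self.ec50)


@dataclass
class UncagingKinetics:
    """Kinetic metrics of a flash-evoked capacitance response."""

    onset_delay: float          # ms after the flash; nan when undetected
    t_max_rate: float           # ms after the flash
    max_rate: float             # fF/ms
    detected: bool = True


def hill_curve(x, vmax, n, ec50):
    x = np.asarray(x, float)
    xn = np.power(np.clip(x, 0, None), n)
    return vmax * xn / (ec50 ** n + xn)


def ogb5n_calibrate(f, fmin, fmax, kd: float = OGB5N_KD_UM):
    """[Ca2+]i (µM) from indicator fluorescence: kd*(f-fmin)/(fmax-f)."""
    f = np.asarray(f, float)
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    if np.any(f >= fmax):
        raise ValueError("fluorescence at or above fmax: indicator saturated")
    if np.any(f < fmin):
        raise ValueError("fluorescence below fmin")
    out = kd * (f - fmin) / (fmax - f)
    return float(out) if out.ndim == 0 else out


def ogb5n_fluorescence(ca, fmin, fmax, kd: float = OGB5N_KD_UM):
    """Inverse calibration: fluorescence expected at a given [Ca2+] (µM)."""
    ca = np.asarray(ca, float)
    if np.any(ca < 0):
        raise ValueError("[Ca2+] must be >= 0")
    out = (fmin * kd + fmax * ca) / (kd + ca)
    return float(out) if out.ndim == 0 else out


def fit_calibration(ca, fratio) -> float:
    """Estimate the indicator K_D (µM) from an F/Fmax vs [Ca2+] titration.

    The calibration relation rearranges to the saturating hyperbola
    F/Fmax = ca/(kd + ca) (for fmin = 0), which is fitted by least squares.
    """
    ca = np.asarray(ca, float)
    fratio = np.asarray(fratio, float)
    if ca.size < 4:
        raise ValueError("need at least 4 calibration concentrations")
    order = np.argsort(ca)
    if np.any(np.diff(fratio[order]) < -0.2):
        raise RuntimeError("calibration data grossly non-monotone")
    popt, _ = optimize.curve_fit(
        lambda x, kd: x / (kd + x), ca, fratio, p0=(np.median(ca),),
        bounds=(1e-6, np.inf), maxfev=10000,
    )
    return float(popt[0])


def release_rate(trace: CmTrace, smooth_win: float = 3.0) -> np.ndarray:
    """Smoothed time derivative of C_m, fF/ms, on the trace's own grid.

    A centered moving average of width ``smooth_win`` ms is applied to the
    first difference; requires uniform sampling.
    """
    dt = trace.dt
    if smooth_win < dt:
        raise ValueError("smooth_win must be at least one sampling interval")
    if np.max(np.abs(np.diff(trace.t) - dt)) > 1e-6 * dt + 1e-9:
        raise ValueError("release_rate requires uniform sampling")
    rate = np.gradient(trace.cm, trace.t)
    w = max(int(round(smooth_win / dt)), 1)
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(rate, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def hill_fit(ca, rate, normalized: bool = False, saturation_frac: float = 0.8) -> HillParams:
    """Fit a Hill function to release rate vs [Ca2+].

    When the fitted curve does not reach ``saturation_frac`` of its own
    plateau within the observed Ca2+ range (a partial fit), the Ca2+
    affinity is instead estimated as the concentration at which the
    max-normalized rate crosses 0.5, and ``fallback_used`` is set.
    """
    ca = np.asarray(ca, float)
    rate = np.asarray(rate, float)
    if ca.size < 5:
        raise ValueError("need at least 5 points")
    if np.all(rate == 0):
        raise ValueError("all rates are zero")
    if normalized:
        rate = rate / rate.max()
    rmax = float(rate.max())
    order = np.argsort(ca)
    half_x = float(np.interp(0.5 * rmax, rate[order], ca[order]))
    p0 = (rmax * 1.05, 2.0, max(half_x, 1e-3))
    try:
        popt, _ = optimize.curve_fit(
            hill_curve, ca, rate, p0=p0,
            bounds=([1e-12, 0.2, 1e-6], [np.inf, 20.0, np.inf]), maxfev=20000,
        )
        vmax, n, ec50 = (float(v) for v in popt)
        fit_failed = False
    except RuntimeError:
        vmax, n, ec50 = rmax, 1.0, max(half_x, 1e-3)
        fit_failed = True
    saturation = hill_curve(ca.max(), 1.0, n, ec50)
    if fit_failed or saturation < saturation_frac:
        # partial sigmoid: report the half-max crossing of the normalized data
        norm = rate / rmax
        ec = float(np.interp(0.5, norm[order], ca[order]))
        return HillParams(vmax=rmax, n=n, ec50=max(ec, 1e-9), fallback_used=True)
    return HillParams(vmax=vmax, n=n, ec50=ec50, fallback_used=False)


def uncaging_metrics(
    trace: CmTrace,
    flash_t: float,
    baseline_sd: float,
    smooth_win: float = 3.0,
    k_onset: float = 3.0,
    min_run: int = 3,
) -> UncagingKinetics:
    """Onset delay, time-to-peak-rate and peak rate of a flash response.

    Onset is the first post-flash time where C_m exceeds the pre-flash
    baseline by ``k_onset`` * ``baseline_sd`` for ``min_run`` consecutive
    samples.  The peak rate is the maximum of the smoothed dC_m/dt after
    the flash.
    """
    if not (trace.t[0] < flash_t < trace.t[-1]):
        raise ValueError("flash_t must lie within the trace")
    if trace.t[-1] - flash_t < 100.0:
        raise ValueError("need at least 100 ms of post-flash recording")
    pre = trace.cm[trace.t < flash_t]
    if pre.size == 0:
        raise ValueError("no pre-flash baseline")
    baseline = float(pre.mean())
    post = trace.t >= flash_t
    t_post = trace.t[post]
    above = trace.cm[post] > baseline + k_onset * baseline_sd
    onset = np.nan
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run:
            onset = float(t_post[i - min_run + 1] - flash_t)
            break
    rate = release_rate(trace, smooth_win=smooth_win)
    r_post = rate[post]
    imax = int(np.argmax(r_post))
    t_max = float(t_post[imax] - flash_t)
    if np.isnan(onset):
        return UncagingKinetics(np.nan, t_max, float(r_post[imax]), detected=False)
    return UncagingKinetics(onset, t_max, float(r_post[imax]), detected=True)
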