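"""Constrained least-squares estimation of the four-pool model parameters.

The objective is the uniform-weight sum of squared differences between an
observed cumulative dC_m curve and the model prediction along the recorded
Ca2+-charge drive.  It is minimized with the Nelder-Mead simplex under box
constraints enforced at every iteration (simplex vertices are clipped to
the box), from multiple seeded random starts.  Parameter uncertainty is
assessed by a Monte-Carlo sensitivity analysis: the observed curve is
resampled point-wise from Normal(mean, sd) and refitted, and per-parameter
means and standard deviations over the runs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import PoolParams
from .stimuli import StimulusProtocol, ObservedCmCurve, model_cm_curve

PARAM_NAMES = (
    "vm1", "vm2", "vm3", "vm4",
    "k1", "k2", "k3", "k4",
    "ca1", "ca2", "ca3", "ca4",
)

_DEFAULT_LOWER = np.array([0, 0, 5e3, 1e4, 0, 0, 0, 0, 0, 0, 0, 0], float)
_DEFAULT_UPPER = np.array(
    [1e5, 1e5, 1e5, 1e5, 1e4, 1e4, 1e4, 1e4, 10, 10, 10, 10], float
)


@dataclass
class FitBounds:
    """Box constraints on (vm1..4, k1..4, ca1..4).

    Defaults: rate coefficients in [0, 1e4]; capacities vm1, vm2 in
    [0, 1e5], vm3 in [5000, 1e5], vm4 in [10000, 1e5]; thresholds in
    [0, 10] (scaled charge units).
    """

    lower: np.ndarray = field(default_factory=lambda: _DEFAULT_LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: _DEFAULT_UPPER.copy())

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if self.lower.shape != (12,) or self.upper.shape != (12,):
            raise ValueError("bounds must be 12-vectors")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, vec, atol: float = 1e-9) -> bool:
        vec = np.asarray(vec, float)
        return bool(
            np.all(vec >= self.lower - atol) and np.all(vec <= self.upper + atol)
        )

    def clip(self, vec) -> np.ndarray:
        return np.clip(np.asarray(vec, float), self.lower, self.upper)


@dataclass
class FitResult:
    params: PoolParams
    sse: float
    n_iter: int
    converged: bool
    start: np.ndarray = None

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


@dataclass
class MonteCarloSummary:
    """Per-parameter mean and sd over Monte-Carlo refits."""

    mean: dict
    sd: dict
    n_runs: int
    seed: int
    samples: np.ndarray = None  # (n_runs, 12), fitted vectors

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


def _vec_to_params(vec, charge_scale: float) -> PoolParams:
    vec = np.asarray(vec, float).copy()
    vec[:4] = np.maximum(vec[:4], 1e-6)  # capacities must stay positive
    return PoolParams.from_vector(vec, charge_scale=charge_scale)


def sse(
    params: PoolParams,
    observed: ObservedCmCurve,
    protocol: StimulusProtocol,
    drive,
    dt: float = 0.1,
    response_delay: float = 50.0,
) -> float:
    """Uniform-weight sum of squared residuals (fF^2) between the observed
    curve and the model prediction.  The per-point sd is deliberately not
    used for weighting."""
    pred = model_cm_curve(params, protocol, drive, dt=dt, response_delay=response_delay)
    if pred.shape != observed.mean.shape:
        raise ValueError("observed curve and protocol sample grid differ in length")
    resid = pred - observed.mean
    return float(resid @ resid)


def draw_starts(bounds: FitBounds, n_starts: int, rng) -> np.ndarray:
    """Seeded random starting vectors inside the box.

    Capacities and rate coefficients are drawn log-uniformly across their
    admissible decades (they span many orders of magnitude); thresholds
    uniformly.  Generation is sequential, so the first k starts of a seed
    are identical for any larger n_starts (nested-seed property).
    """
    starts = np.empty((n_starts, 12))
    lo = bounds.lower.copy()
    hi = bounds.upper.copy()
    log_floor = np.array([10.0, 10.0, 10.0, 10.0, 1e-4, 1e-4, 1e-4, 1e-4])
    for s in range(n_starts):
        v = np.empty(12)
        for j in range(8):  # vm and k: log-uniform
            a = max(lo[j], log_floor[j])
            b = max(hi[j], a * 10)
            v[j] = np.exp(rng.uniform(np.log(a), np.log(b)))
        for j in range(8, 12):  # thresholds: uniform
            v[j] = rng.uniform(lo[j], hi[j])
        starts[s] = bounds.clip(v)
    return starts


def heuristic_start(
    observed: ObservedCmCurve,
    protocol: StimulusProtocol,
    drive,
    bounds: FitBounds,
    charge_scale: float = 1e-12,
) -> np.ndarray:
    """Data-driven starting vector read off the curve's phase structure.

    For train curves: the RRP capacity is taken from the early depletion
    plateau, the superlinear-onset charge seeds the reserve-pool
    thresholds, and the first-pulse charge seeds the recycling-pool
    threshold.  Other protocols get a generic mid-scale start with
    thresholds spread over the observed charge range.
    """
    from .model import cm_to_vesicles

    d = drive[0] if isinstance(drive, (list, tuple)) else drive
    q_end = float(d.q[-1]) / charge_scale
    n = cm_to_vesicles(np.clip(observed.mean, 0, None))
    if protocol.kind == "train" and n.size >= 10:
        ts = protocol.sample_times()
        qs = np.interp(ts, d.t, d.q) / charge_scale
        vm1 = max(float(n[2]), 10.0)
        inc = np.diff(n)
        med = max(float(np.median(inc[2: min(22, inc.size)])), 1e-3)
        onset = next(
            (i for i in range(min(25, inc.size - 1), inc.size) if inc[i] > 2 * med),
            int(0.8 * inc.size),
        )
        ca3 = 0.9 * float(qs[onset])
        x0 = np.array([
            vm1, 10 * vm1, 2e4, 1.5e4,
            200.0, 5.0, 5.0, 1e-2,
            0.02 * q_end, float(qs[0]), ca3, ca3,
        ])
    else:
        x0 = np.array([
            1e3, 5e3, 2e4, 1.5e4,
            200.0, 5.0, 5.0, 1e-2,
            0.01 * q_end, 0.1 * q_end, 0.5 * q_end, 0.6 * q_end,
        ])
    return bounds.clip(x0)


def fit(
    observed: ObservedCmCurve,
    protocol: StimulusProtocol,
    drive,
    bounds: FitBounds | None = None,
    n_starts: int = 20,
    seed: int = 0,
    dt: float = 0.1,
    maxfev: int = 3000,
    charge_scale: float = 1e-12,
    extra_starts=None,
    use_heuristic: bool = True,
    polish: bool = True,
    polish_maxfev: int = 20000,
    n_polish: int = 4,
    response_delay: float = 50.0,
) -> FitResult:
    """Best-of-multi-start bounded Nelder-Mead fit of all 12 parameters.

    Starts are: an optional data-driven heuristic start, any
    ``extra_starts`` (e.g. a warm start for Monte-Carlo refits), then
    ``n_starts`` seeded random draws.  With ``polish`` the simplex is
    restarted from the incumbent best point up to ``n_polish`` times (a
    fresh simplex recovers from premature collapse, which Nelder-Mead is
    prone to in 12 dimensions).
    """
    bounds = bounds or FitBounds()
    rng = np.random.default_rng(seed)

    def objective(vec):
        try:
            p = _vec_to_params(vec, charge_scale)
            return sse(p, observed, protocol, drive, dt=dt, response_delay=response_delay)
        except (ValueError, FloatingPointError):
            return 1e30

    start_list = []
    if use_heuristic:
        start_list.append(heuristic_start(observed, protocol, drive, bounds, charge_scale))
    start_list += [bounds.clip(np.asarray(s, float)) for s in (extra_starts or [])]
    start_list += list(draw_starts(bounds, n_starts, rng))
    sci_bounds = optimize.Bounds(bounds.lower, bounds.upper)
    best = None
    best_start = start_list[0]
    n_iter_total = 0
    converged = False
    for x0 in start_list:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead", bounds=sci_bounds,
            options={"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-10, "adaptive": True},
        )
        n_iter_total += res.nit
        if best is None or res.fun < best.fun:
            best = res
            best_start = x0
        converged = converged or bool(res.success)
    if polish:
        for _ in range(n_polish):
            res = optimize.minimize(
                objective, best.x, method="Nelder-Mead", bounds=sci_bounds,
                options={"maxfev": polish_maxfev, "xatol": 1e-9, "fatol": 1e-13,
                         "adaptive": True},
            )
            n_iter_total += res.nit
            improved = res.fun < best.fun * (1 - 1e-9) - 1e-12
            if res.fun < best.fun:
                best = res
                converged = converged or bool(res.success)
            if not improved:
                break
    xbest = bounds.clip(best.x)
    return FitResult(
        params=_vec_to_params(xbest, charge_scale),
        sse=float(best.fun),
        n_iter=int(n_iter_total),
        converged=converged,
        start=np.asarray(best_start),
    )


def monte_carlo(
    observed: ObservedCmCurve,
    protocol: StimulusProtocol,
    drive,
    bounds: FitBounds | None = None,
    n_runs: int = 60,
    seed: int = 0,
    base_fit: FitResult | None = None,
    n_starts: int = 0,
    dt: float = 0.1,
    maxfev: int = 2000,
    charge_scale: float = 1e-12,
) -> MonteCarloSummary:
    """Monte-Carlo sensitivity analysis of the fit.

    Each run resamples every observed point from Normal(mean, sd) -- a
    plain Gaussian, so negative excursions are kept -- and refits.  Refits
    are warm-started from the base fit (computed here when not supplied)
    plus ``n_starts`` random starts.  Reports per-parameter mean and sd
    over the runs.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    bounds = bounds or FitBounds()
    if base_fit is None:
        base_fit = fit(
            observed, protocol, drive, bounds=bounds, seed=seed, dt=dt,
            charge_scale=charge_scale,
        )
    warm = base_fit.params.to_vector()
    rng = np.random.default_rng(seed)
    samples = np.empty((n_runs, 12))
    for r in range(n_runs):
        resampled = ObservedCmCurve(
            x=observed.x,
            mean=rng.normal(observed.mean, observed.sd),
            sd=observed.sd,
        )
        run_seed = int(rng.integers(0, 2**31 - 1))
        res = fit(
            resampled, protocol, drive, bounds=bounds, n_starts=n_starts,
            seed=run_seed, dt=dt, maxfev=maxfev, charge_scale=charge_scale,
            extra_starts=[warm], use_heuristic=False,
            polish=True, n_polish=1, polish_maxfev=maxfev,
        )
        samples[r] = res.params.to_vector()
    mean = dict(zip(PARAM_NAMES, samples.mean(axis=0)))
    sd = dict(zip(PARAM_NAMES, samples.std(axis=0, ddof=1)))
    return MonteCarloSummary(mean=mean, sd=sd, n_runs=n_runs, seed=seed, samples=samples)
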