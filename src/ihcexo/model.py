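"""Four-pool mass-action model of vesicle trafficking and fusion at the
inner-hair-cell ribbon synapse.

The model tracks four vesicle pools feeding the fusion site in series --
readily releasable pool (pool 1), recycling pool (pool 2), reserve pool
(pool 3) and a distant reservoir (pool 4).  Every transition rate is driven
by the cumulative Ca2+ charge q(t) (the integral of the Ca2+ current, used
as a proxy for intracellular [Ca2+] when the diffusion volume is taken as a
unit volume)::

    K_i(t) = k_i * max(q(t) - ca_i, 0)          i = 1..4

and the pool occupancies V_i(t) and cumulative fused count F(t) obey

    dF/dt  = K1 V1
    dV1/dt = K2 V2 (1 - V1/VM1) - K1 V1
    dV2/dt = K3 V3 (1 - V2/VM2) - K2 V2 (1 - V1/VM1)
    dV3/dt = K4 V4 (1 - V3/VM3) - K3 V3 (1 - V2/VM2)
    dV4/dt =                    - K4 V4 (1 - V3/VM3)

with F(0) = 0 and V_i(0) = VM_i.  The right-hand sides sum to zero, so
F + sum(V_i) is conserved.

Charge unit
-----------
Rates and thresholds are expressed in a scaled charge unit defined by
``PoolParams.charge_scale`` (default 1 pC = 1e-12 C).  Drives handed to
:func:`simulate` carry SI coulombs and are divided by ``charge_scale``
internally; :func:`effective_rates` operates directly in the params' unit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

try:  # optional JIT; the pure-python path is the same function
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


#: membrane capacitance of one synaptic vesicle, fF (45 aF)
VESICLE_CAPACITANCE_FF = 0.045


class ConvergenceWarning(UserWarning):
    """Raised when the fixed-step integrator fails its dt/2 self-check."""


@dataclass
class PoolParams:
    """Rate constants, Ca2+ thresholds and capacities of the four pools.

    ``vm1..vm4`` are pool capacities in vesicles; ``k1..k4`` are
    Ca2+-independent rate coefficients (per charge unit per second);
    ``ca1..ca4`` are the minimum cumulative charges that recruit each pool,
    in the charge unit defined by ``charge_scale`` (coulombs per unit).
    """

    vm1: float
    vm2: float
    vm3: float
    vm4: float
    k1: float
    k2: float
    k3: float
    k4: float
    ca1: float
    ca2: float
    ca3: float
    ca4: float
    charge_scale: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("vm1", "vm2", "vm3", "vm4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ca1", "ca2", "ca3", "ca4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.charge_scale <= 0:
            raise ValueError("charge_scale must be > 0")

    @property
    def capacities(self) -> np.ndarray:
        return np.array([self.vm1, self.vm2, self.vm3, self.vm4], float)

    @property
    def rate_coeffs(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4], float)

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([self.ca1, self.ca2, self.ca3, self.ca4], float)

    @property
    def thresholds_coulomb(self) -> np.ndarray:
        """Thresholds expressed in SI coulombs."""
        return self.thresholds * self.charge_scale

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 12-vector (vm1..4, k1..4, ca1..4)."""
        return np.concatenate([self.capacities, self.rate_coeffs, self.thresholds])

    @classmethod
    def from_vector(cls, vec, charge_scale: float = 1e-12) -> "PoolParams":
        vec = np.asarray(vec, float)
        if vec.shape != (12,):
            raise ValueError("expected a 12-vector (vm1..4, k1..4, ca1..4)")
        return cls(*vec, charge_scale=charge_scale)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "PoolParams":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                data = json.loads(s)
            else:
                with open(s) as fh:
                    data = json.load(fh)
        return cls(**data)


def reference_params(genotype: str = "control") -> PoolParams:
    """Published parameter sets of the model for the two genotypes.

    ``control`` is the phenotypically normal heterozygote, ``mutant`` the
    C2C-domain homozygous mutant.  Thresholds are stored in the 1 pC charge
    unit (so 1.7e-14 C becomes 0.017), which places all of them inside the
    fitting box [0, 10].
    """
    if genotype == "control":
        return PoolParams(
            vm1=616, vm2=1602, vm3=16772, vm4=11491,
            k1=1062, k2=6.4, k3=4.5, k4=6.6e-3,
            ca1=0.017, ca2=0.83, ca3=8.7, ca4=9.7,
        )
    if genotype == "mutant":
        return PoolParams(
            vm1=570, vm2=1877, vm3=11312, vm4=14171,
            k1=349, k2=0.8, k3=0.95, k4=8.5e-3,
            ca1=0.021, ca2=0.67, ca3=10.2, ca4=9.7,
        )
    raise ValueError("genotype must be 'control' or 'mutant'")


@dataclass
class PoolState:
    """Instantaneous pool occupancies and cumulative fused count."""

    v1: float
    v2: float
    v3: float
    v4: float
    fused: float = 0.0

    @property
    def total(self) -> float:
        return self.fused + self.v1 + self.v2 + self.v3 + self.v4


@dataclass
class RateVector:
    """Instantaneous Ca2+-gated transition rates, 1/s."""

    K1: float
    K2: float
    K3: float
    K4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.K2, self.K3, self.K4], float)


@dataclass
class CalciumDrive:
    """Cumulative Ca2+ charge q(t): t in ms, q in coulombs.

    q must start at zero and be non-decreasing (the drive is the running
    integral of the rectified Ca2+ current and never decays).
    """

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.q = np.asarray(self.q, float)
        if self.t.ndim != 1 or self.t.shape != self.q.shape:
            raise ValueError("t and q must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("drive needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("drive contains non-finite charge values")
        qmax = float(np.max(np.abs(self.q)))
        if np.any(np.diff(self.q) < -1e-9 * qmax):
            raise ValueError("cumulative charge must be non-decreasing")
        if abs(self.q[0]) > 1e-9 * qmax:
            raise ValueError("cumulative charge must start at 0")

    def resample(self, t_new: np.ndarray) -> np.ndarray:
        return np.interp(t_new, self.t, self.q)


@dataclass
class Trajectory:
    """Simulated time course: occupancies, cumulative fusion, capacitance."""

    t: np.ndarray
    v: np.ndarray            # shape (n, 4)
    fused: np.ndarray        # shape (n,)
    cm: np.ndarray = field(default=None)  # fF, 0.045 * fused

    def __post_init__(self) -> None:
        if self.cm is None:
            self.cm = fused_to_cm(self.fused)

    def state_at(self, i: int) -> PoolState:
        return PoolState(*self.v[i], fused=float(self.fused[i]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.t,
                "v1": self.v[:, 0],
                "v2": self.v[:, 1],
                "v3": self.v[:, 2],
                "v4": self.v[:, 3],
                "fused": self.fused,
                "cm_fF": self.cm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def effective_rates(params: PoolParams, q: float) -> RateVector:
    """Threshold-linear Ca2+ gating: K_i = k_i * max(q - ca_i, 0).

    ``q`` is the cumulative charge in the params' charge unit.  Below its
    threshold each pool is silent; above it the rate grows linearly with the
    excess charge.
    """
    if q < 0:
        raise ValueError("cumulative charge must be >= 0")
    k = params.rate_coeffs
    ca = params.thresholds
    return RateVector(*(k * np.maximum(q - ca, 0.0)))


@njit(cache=True)
def _integrate_rk4(q_grid, dt_s, vm, k, ca):
    """Classic RK4 on the 5-state system over a uniform grid.

    ``q_grid`` holds the scaled drive at every grid node; rates use the
    midpoint value for the two middle RK stages.  Occupancies are clamped
    to [0, VM] after each step (rounding-level overshoots only).  The
    right-hand side is inlined in scalar form for speed.
    """
    n = q_grid.shape[0]
    y = np.empty((n, 5))
    vm1, vm2, vm3, vm4 = vm[0], vm[1], vm[2], vm[3]
    k1c, k2c, k3c, k4c = k[0], k[1], k[2], k[3]
    ca1, ca2, ca3, ca4 = ca[0], ca[1], ca[2], ca[3]
    f = 0.0
    v1, v2, v3, v4 = vm1, vm2, vm3, vm4
    y[0, 0] = f
    y[0, 1] = v1
    y[0, 2] = v2
    y[0, 3] = v3
    y[0, 4] = v4
    for i in range(n - 1):
        qa = q_grid[i]
        qb = q_grid[i + 1]
        qm = 0.5 * (qa + qb)
        df = 0.0
        dv1 = 0.0
        dv2 = 0.0
        dv3 = 0.0
        dv4 = 0.0
        s1 = s2 = s3 = s4 = 0.0
        # four RK stages; stage weights 1,2,2,1
        for s in range(4):
            if s == 0:
                q = qa
                h = 0.0
                w = 1.0
            elif s == 1:
                q = qm
                h = 0.5 * dt_s
                w = 2.0
            elif s == 2:
                q = qm
                h = 0.5 * dt_s
                w = 2.0
            else:
                q = qb
                h = dt_s
                w = 1.0
            if s == 0:
                u1, u2, u3, u4 = v1, v2, v3, v4
            else:
                u1 = v1 + h * s1
                u2 = v2 + h * s2
                u3 = v3 + h * s3
                u4 = v4 + h * s4
            K1 = k1c * max(q - ca1, 0.0)
            K2 = k2c * max(q - ca2, 0.0)
            K3 = k3c * max(q - ca3, 0.0)
            K4 = k4c * max(q - ca4, 0.0)
            f1 = K1 * u1
            f2 = K2 * u2 * ((vm1 - u1) / vm1)
            f3 = K3 * u3 * ((vm2 - u2) / vm2)
            f4 = K4 * u4 * ((vm3 - u3) / vm3)
            s0 = f1
            s1 = f2 - f1
            s2 = f3 - f2
            s3 = f4 - f3
            s4 = -f4
            df += w * s0
            dv1 += w * s1
            dv2 += w * s2
            dv3 += w * s3
            dv4 += w * s4
        c = dt_s / 6.0
        f = max(f + c * df, f)  # cumulative fusion cannot decrease
        v1 = min(max(v1 + c * dv1, 0.0), vm1)
        v2 = min(max(v2 + c * dv2, 0.0), vm2)
        v3 = min(max(v3 + c * dv3, 0.0), vm3)
        v4 = min(max(v4 + c * dv4, 0.0), vm4)
        y[i + 1, 0] = f
        y[i + 1, 1] = v1
        y[i + 1, 2] = v2
        y[i + 1, 3] = v3
        y[i + 1, 4] = v4
    return y


def simulate(
    params: PoolParams,
    drive: CalciumDrive,
    dt: float = 0.05,
    t_end: float | None = None,
    check_convergence: bool = False,
) -> Trajectory:
    """Integrate the five coupled pool equations along a Ca2+ drive.

    Parameters
    ----------
    params : PoolParams
        Model parameters; thresholds/rates in the params' charge unit.
    drive : CalciumDrive
        Cumulative charge vs time (ms, coulombs); linearly interpolated
        onto the simulation grid.
    dt : float
        Fixed RK4 step, ms.
    t_end : float, optional
        End of the simulated span; defaults to the end of the drive.
    check_convergence : bool
        If True, re-integrate at dt/2 and warn (ConvergenceWarning) when
        the final fused counts disagree by more than 0.5%.

    Returns
    -------
    Trajectory
        Uniform grid starting at drive.t[0] with pool occupancies,
        cumulative fused vesicles and the equivalent capacitance (fF).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end is None:
        t_end = float(drive.t[-1])
    if t_end > drive.t[-1] + 1e-9:
        raise ValueError("drive does not cover the requested time span")
    n = int(round((t_end - drive.t[0]) / dt)) + 1
    t = drive.t[0] + dt * np.arange(n)
    q_scaled = drive.resample(t) / params.charge_scale
    y = _integrate_rk4(
        q_scaled, dt * 1e-3, params.capacities, params.rate_coeffs, params.thresholds
    )
    if check_convergence:
        t2 = drive.t[0] + (dt / 2) * np.arange(2 * n - 1)
        q2 = drive.resample(t2) / params.charge_scale
        y2 = _integrate_rk4(
            q2, dt * 0.5e-3, params.capacities, params.rate_coeffs, params.thresholds
        )
        f1, f2 = y[-1, 0], y2[-1, 0]
        scale = max(abs(f2), 1e-9)
        if abs(f1 - f2) / scale > 0.005:
            warnings.warn(
                f"integration step dt={dt} ms fails the dt/2 self-check "
                f"(fused {f1:.4g} vs {f2:.4g}); reduce dt",
                ConvergenceWarning,
            )
    return Trajectory(t=t, v=y[:, 1:], fused=y[:, 0])


def fused_to_cm(count):
    """Convert a fused-vesicle count to membrane capacitance, fF (45 aF each)."""
    count = np.asarray(count, float)
    if np.any(count < 0):
        raise ValueError("vesicle count must be >= 0")
    out = VESICLE_CAPACITANCE_FF * count
    return float(out) if out.ndim == 0 else out


def cm_to_vesicles(cm):
    """Convert a capacitance (fF) to the equivalent vesicle count."""
    cm = np.asarray(cm, float)
    if np.any(cm < 0):
        raise ValueError("capacitance must be >= 0")
    out = cm / VESICLE_CAPACITANCE_FF
    return float(out) if out.ndim == 0 else out
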