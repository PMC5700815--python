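"""Geometric analysis of ribbon-synapse reconstructions and dual-channel
point patterns.

Synaptic vesicles from a 3D reconstruction are assigned to the classical
pools by distance rules: the readily releasable pool (RRP, centers within
40 nm of the presynaptic membrane and within 80 nm of the active-zone
center along the membrane), the ribbon-attached pool (RAP, within 80 nm of
the ribbon surface and not membrane-apposed) and the outlying pool (OP,
80-350 nm from the ribbon, not membrane-apposed).  Shell densities around
the ribbon are computed with a voxelized distance transform.  For STED
spot patterns, nearest-neighbour distance distributions and their
Kolmogorov-Smirnov comparison quantify colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.spatial import cKDTree


@dataclass
class Ellipsoid:
    """Triaxial ellipsoid (ribbon surface model): center, semiaxes, rotation."""

    center: np.ndarray
    semiaxes: np.ndarray             # (a, b, c), nm
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.semiaxes = np.asarray(self.semiaxes, float)
        self.rotation = np.asarray(self.rotation, float)
        if np.any(self.semiaxes <= 0):
            raise ValueError("semiaxes must be > 0")

    def to_local(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float)) - self.center
        return p @ self.rotation

    def contains(self, points) -> np.ndarray:
        u = self.to_local(points) / self.semiaxes
        return np.sum(u * u, axis=1) < 1.0

    def surface_distance(self, points) -> np.ndarray:
        """Exact unsigned Euclidean distance from points to the surface.

        Solves, per point, the normal-projection root equation
        sum_i (a_i u_i / (t + a_i^2))^2 = 1 by bracketed root finding
        (monotone in t), valid inside and outside.
        """
        u = np.abs(self.to_local(points))
        a = self.semiaxes
        a2 = a * a
        out = np.empty(u.shape[0])
        amin2 = float(np.min(a2))
        for i, p in enumerate(u):
            if np.all(p < 1e-12):
                out[i] = float(np.min(a))
                continue

            def F(t, p=p):
                return float(np.sum((a * p / (t + a2)) ** 2) - 1.0)

            lo = -amin2 + 1e-9 * amin2
            while F(lo) < 0:  # point extremely close to the center axis
                lo = -amin2 + (lo + amin2) * 0.1
                if lo <= -amin2 * (1 - 1e-15):
                    break
            hi = float(np.linalg.norm(a * p) + np.max(a2))
            while F(hi) > 0:
                hi *= 2.0
            t = optimize.brentq(F, lo, hi, xtol=1e-10, rtol=1e-12)
            closest = a2 * p / (t + a2)
            out[i] = float(np.linalg.norm(closest - p))
        return out


@dataclass
class SynapseScene:
    """3D reconstruction: vesicle centers, membrane plane, ribbon, AZ center.

    The presynaptic membrane is the plane through ``membrane_point`` with
    unit normal ``membrane_normal`` pointing into the cytoplasm; the
    active-zone center lies on that plane.  Coordinates in nm.
    """

    vesicles: np.ndarray                    # (n, 3) nm
    ribbon: Ellipsoid
    az_center: np.ndarray
    membrane_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    membrane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    vesicle_radius: float = 20.0            # metadata only; rules are center-based

    def __post_init__(self) -> None:
        self.vesicles = np.asarray(self.vesicles, float).reshape(-1, 3)
        self.az_center = np.asarray(self.az_center, float)
        self.membrane_point = np.asarray(self.membrane_point, float)
        n = np.asarray(self.membrane_normal, float)
        self.membrane_normal = n / np.linalg.norm(n)
        if abs(np.dot(self.az_center - self.membrane_point, self.membrane_normal)) > 1e-6:
            raise ValueError("az_center must lie on the membrane plane")
        if self.vesicles.size and np.any(self.ribbon.contains(self.vesicles)):
            raise ValueError("ribbon intersects vesicle centers")

    def membrane_distance(self, points=None) -> np.ndarray:
        p = self.vesicles if points is None else np.atleast_2d(np.asarray(points, float))
        return np.abs((p - self.membrane_point) @ self.membrane_normal)

    def az_lateral_distance(self, points=None) -> np.ndarray:
        """Distance to the AZ center measured along the membrane plane."""
        p = self.vesicles if points is None else np.atleast_2d(np.asarray(points, float))
        d = p - self.az_center
        d_in_plane = d - np.outer(d @ self.membrane_normal, self.membrane_normal)
        return np.linalg.norm(d_in_plane, axis=1)

    def ribbon_distance(self, points=None) -> np.ndarray:
        p = self.vesicles if points is None else points
        if self.vesicles.size == 0 and points is None:
            return np.empty(0)
        return self.ribbon.surface_distance(p)


@dataclass
class PoolAssignment:
    labels: np.ndarray                      # "RRP" | "RAP" | "OP" | "none"
    counts: dict
    densities: dict = field(default_factory=dict)  # shell -> vesicles/µm^3

    def indices(self, pool: str) -> np.ndarray:
        return np.nonzero(self.labels == pool)[0]


@dataclass
class SpotField:
    """2D point pattern from one imaging channel (nm)."""

    points: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")


@dataclass
class ColocResult:
    d_ab: np.ndarray        # each a-spot to nearest b-spot, nm
    d_bb: np.ndarray        # each b-spot to nearest other b-spot, nm
    ks_stat: float
    p_value: float
    mode_ab: float
    mode_bb: float


def classify_pools(
    scene: SynapseScene,
    rrp_membrane_max: float = 40.0,
    rrp_az_max: float = 80.0,
    rap_ribbon_max: float = 80.0,
    op_ribbon_max: float = 350.0,
    rap_excludes_membrane_apposed: bool = True,
) -> PoolAssignment:
    """Assign each vesicle to RRP, RAP, OP or none by the distance rules.

    RRP: membrane distance <= 40 nm and within 80 nm of the AZ center
    along the membrane.  RAP: ribbon-surface distance <= 80 nm, excluding
    membrane-apposed vesicles (or only RRP members, when
    ``rap_excludes_membrane_apposed`` is False).  OP: ribbon distance in
    (80, 350] nm, excluding membrane-apposed vesicles.
    """
    n = scene.vesicles.shape[0]
    labels = np.full(n, "none", dtype=object)
    if n:
        d_mem = scene.membrane_distance()
        d_az = scene.az_lateral_distance()
        d_rib = scene.ribbon_distance()
        apposed = d_mem <= rrp_membrane_max
        rrp = apposed & (d_az <= rrp_az_max)
        rap_excl = apposed if rap_excludes_membrane_apposed else rrp
        rap = (d_rib <= rap_ribbon_max) & ~rap_excl
        op = (d_rib > rap_ribbon_max) & (d_rib <= op_ribbon_max) & ~apposed
        labels[rrp] = "RRP"
        labels[rap] = "RAP"
        labels[op] = "OP"
    labels = labels.astype(str)
    counts = {p: int(np.sum(labels == p)) for p in ("RRP", "RAP", "OP", "none")}
    return PoolAssignment(labels=labels, counts=counts)


def shell_densities(
    scene: SynapseScene,
    shell_edges,
    voxel: float = 5.0,
    clip_below_membrane: bool = True,
) -> dict:
    """Vesicle density (vesicles/µm^3) in distance shells around the ribbon.

    Shell volumes come from a voxelized Euclidean distance transform of
    the ribbon (voxel size ``voxel`` nm); vesicle counts use exact
    center-to-surface distances.  Volume below the presynaptic membrane
    (outside the cell) is excluded by default.
    """
    edges = np.asarray(shell_edges, float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("shell_edges must be increasing with >= 2 entries")
    margin = edges[-1] + 2 * voxel
    lo = scene.ribbon.center - (np.max(scene.ribbon.semiaxes) + margin)
    hi = scene.ribbon.center + (np.max(scene.ribbon.semiaxes) + margin)
    axes = [np.arange(lo[d], hi[d] + voxel, voxel) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = scene.ribbon.contains(pts).reshape(X.shape)
    if not inside.any():
        raise ValueError("voxel grid does not resolve the ribbon; reduce voxel size")
    dist = ndimage.distance_transform_edt(~inside, sampling=voxel)
    keep = ~inside
    if clip_below_membrane:
        side = ((pts - scene.membrane_point) @ scene.membrane_normal).reshape(X.shape)
        keep &= side > 0
    d_ves = scene.ribbon_distance() if scene.vesicles.size else np.empty(0)
    out = {}
    for a, b in zip(edges[:-1], edges[1:]):
        vox = keep & (dist > a) & (dist <= b)
        vol_um3 = vox.sum() * voxel**3 * 1e-9
        count = int(np.sum((d_ves > a) & (d_ves <= b)))
        out[(float(a), float(b))] = count / vol_um3 if vol_um3 > 0 else np.nan
    return out


def pool_distances(scene: SynapseScene, assignment: PoolAssignment):
    """Mean RRP-center-to-membrane and RAP-center-to-ribbon distances (nm).

    Empty pools yield nan.
    """
    rrp = assignment.indices("RRP")
    rap = assignment.indices("RAP")
    d_rrp = (
        float(scene.membrane_distance(scene.vesicles[rrp]).mean()) if rrp.size else np.nan
    )
    d_rap = (
        float(scene.ribbon_distance(scene.vesicles[rap]).mean()) if rap.size else np.nan
    )
    return d_rrp, d_rap


def _mode(d: np.ndarray, bin_width: float) -> float:
    if d.max() <= 0:
        return 0.0
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def nn_colocalization(a: SpotField, b: SpotField, mode_bin: float = 20.0) -> ColocResult:
    """Nearest-neighbour colocalization statistic for two channels.

    Computes the distance from every a-spot to its nearest b-spot and from
    every b-spot to its nearest *other* b-spot, compares the two
    distributions with a two-sample KS test, and reports histogram modes
    (bin width ``mode_bin`` nm).
    """
    if a.points.shape[0] < 2 or b.points.shape[0] < 2:
        raise ValueError("need at least 2 spots per field")
    tree = cKDTree(b.points)
    d_ab, _ = tree.query(a.points, k=1)
    d_bb_all, _ = tree.query(b.points, k=2)
    d_bb = d_bb_all[:, 1]
    ks = stats.ks_2samp(d_ab, d_bb)
    return ColocResult(
        d_ab=d_ab,
        d_bb=d_bb,
        ks_stat=float(ks.statistic),
        p_value=float(ks.pvalue),
        mode_ab=_mode(d_ab, mode_bin),
        mode_bb=_mode(d_bb, mode_bin),
    )


def default_geometry() -> dict:
    """Plate-shaped ribbon hovering 50 nm above the membrane, AZ at origin."""
    return {
        "ribbon": Ellipsoid(center=[0.0, 0.0, 190.0], semiaxes=[110.0, 190.0, 140.0]),
        "az_center": np.zeros(3),
        "membrane_point": np.zeros(3),
        "membrane_normal": np.array([0.0, 0.0, 1.0]),
    }


def generate_scene(
    pool_counts=(14, 42, 33),
    geometry: dict | None = None,
    seed: int = 0,
    max_tries: int = 200000,
) -> SynapseScene:
    """Synthetic tomogram stand-in with exact ground-truth pool counts.

    Vesicle centers are rejection-sampled uniformly within each pool's
    defining region, so re-classifying the scene recovers ``pool_counts``
    exactly.  Raises when a region cannot host the requested count.
    """
    geo = geometry or default_geometry()
    rng = np.random.default_rng(seed)
    probe = SynapseScene(vesicles=np.empty((0, 3)), **geo)
    rib = probe.ribbon
    n_rrp, n_rap, n_op = (int(c) for c in pool_counts)
    if min(n_rrp, n_rap, n_op) < 0:
        raise ValueError("pool counts must be >= 0")

    def accept(p, pool):
        p = p[None, :]
        side = float((p[0] - probe.membrane_point) @ probe.membrane_normal)
        if side <= 0:  # outside the cytoplasm
            return False
        d_mem = probe.membrane_distance(p)[0]
        d_az = probe.az_lateral_distance(p)[0]
        if rib.contains(p)[0]:
            return False
        d_rib = rib.surface_distance(p)[0]
        apposed = d_mem <= 40.0
        if pool == "RRP":
            return apposed and d_az <= 80.0
        if pool == "RAP":
            return (d_rib <= 80.0) and not apposed
        return (80.0 < d_rib <= 350.0) and not apposed

    boxes = {
        "RRP": (np.array([-80.0, -80.0, 0.0]) + probe.az_center,
                np.array([80.0, 80.0, 40.0]) + probe.az_center),
        "RAP": (rib.center - rib.semiaxes.max() - 80.0,
                rib.center + rib.semiaxes.max() + 80.0),
        "OP": (rib.center - rib.semiaxes.max() - 350.0,
               rib.center + rib.semiaxes.max() + 350.0),
    }
    vesicles = []
    for pool, count in (("RRP", n_rrp), ("RAP", n_rap), ("OP", n_op)):
        lo, hi = boxes[pool]
        placed = 0
        for _ in range(max_tries):
            if placed == count:
                break
            p = rng.uniform(lo, hi)
            if accept(p, pool):
                vesicles.append(p)
                placed += 1
        if placed < count:
            raise RuntimeError(
                f"infeasible geometry: could not place {count} {pool} vesicles"
            )
    ves = np.array(vesicles) if vesicles else np.empty((0, 3))
    return SynapseScene(vesicles=ves, **geo)


def generate_spots(
    n_b: int = 200,
    coloc_fraction: float = 0.5,
    jitter_sd: float = 50.0,
    field_size: float = 5000.0,
    seed: int = 0,
    n_a: int | None = None,
):
    """Synthetic STED stand-in: channel b uniform; a fraction of channel a
    spots are jittered copies of b-spots, the rest uniform background.

    Returns (SpotField a, SpotField b).
    """
    if n_b < 0 or (n_a is not None and n_a < 0):
        raise ValueError("counts must be >= 0")
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_a = n_b if n_a is None else n_a
    b = rng.uniform(0.0, field_size, size=(n_b, 2))
    n_coloc = int(round(coloc_fraction * n_a))
    idx = rng.choice(n_b, size=n_coloc, replace=True)
    a_coloc = b[idx] + rng.normal(0.0, jitter_sd, size=(n_coloc, 2))
    a_bg = rng.uniform(0.0, field_size, size=(n_a - n_coloc, 2))
    a = np.vstack([a_coloc, a_bg])
    return SpotField(points=a, channel="a"), SpotField(points=b, channel="b")
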