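"""Brute-force geometric oracles shared by the spatial and acceptance tests.

Kept deliberately independent of the package's own distance routines: the
surface distance is found by direct minimization over the parametrized
ellipsoid surface, and classification re-applies the distance rules from
scratch.
"""

import numpy as np
from scipy import optimize


def brute_force_surface_distance(ellipsoid, point):
    a = ellipsoid.semiaxes
    p = ellipsoid.to_local(point)[0]

    def surf(ang):
        th, ph = ang
        return np.array([
            a[0] * np.sin(th) * np.cos(ph),
            a[1] * np.sin(th) * np.sin(ph),
            a[2] * np.cos(th),
        ])

    th = np.linspace(0, np.pi, 80)
    ph = np.linspace(0, 2 * np.pi, 160)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack([
        a[0] * np.sin(TH) * np.cos(PH),
        a[1] * np.sin(TH) * np.sin(PH),
        a[2] * np.cos(TH),
    ], axis=-1).reshape(-1, 3)
    i0 = np.argmin(np.sum((pts - p) ** 2, axis=1))
    x0 = np.array([TH.ravel()[i0], PH.ravel()[i0]])
    res = optimize.minimize(lambda ang: np.sum((surf(ang) - p) ** 2), x0,
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    return float(np.sqrt(res.fun))


def brute_force_classify(scene):
    labels = []
    for p in scene.vesicles:
        d_mem = float(scene.membrane_distance(p[None, :])[0])
        d_az = float(scene.az_lateral_distance(p[None, :])[0])
        d_rib = brute_force_surface_distance(scene.ribbon, p)
        apposed = d_mem <= 40.0
        if apposed and d_az <= 80.0:
            labels.append("RRP")
        elif d_rib <= 80.0 and not apposed:
            labels.append("RAP")
        elif 80.0 < d_rib <= 350.0 and not apposed:
            labels.append("OP")
        else:
            labels.append("none")
    return np.array(labels)
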