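"""Delimited-text and JSON entry points for real or synthesized data."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .model import CalciumDrive, PoolParams
from .cm_analysis import CmTrace
from .stimuli import CurrentTrace, ObservedCmCurve, IVParams


def read_current_trace(path) -> CurrentTrace:
    df = pd.read_csv(path)
    return CurrentTrace(t=df["t_ms"].to_numpy(), i=df["i_pA"].to_numpy())


def write_current_trace(trace: CurrentTrace, path) -> None:
    pd.DataFrame({"t_ms": trace.t, "i_pA": trace.i}).to_csv(path, index=False)


def read_drive(path) -> CalciumDrive:
    df = pd.read_csv(path)
    return CalciumDrive(t=df["t_ms"].to_numpy(), q=df["q_C"].to_numpy())


def write_drive(drive: CalciumDrive, path) -> None:
    pd.DataFrame({"t_ms": drive.t, "q_C": drive.q}).to_csv(path, index=False)


def read_cm_trace(path, stim_marks=None) -> CmTrace:
    df = pd.read_csv(path)
    return CmTrace(
        t=df["t_ms"].to_numpy(), cm=df["cm_fF"].to_numpy(), stim_marks=stim_marks or []
    )


def write_cm_trace(trace: CmTrace, path) -> None:
    pd.DataFrame({"t_ms": trace.t, "cm_fF": trace.cm}).to_csv(path, index=False)


def read_observed_curve(path) -> ObservedCmCurve:
    df = pd.read_csv(path)
    return ObservedCmCurve(
        x=df["x"].to_numpy(), mean=df["mean_fF"].to_numpy(), sd=df["sd_fF"].to_numpy()
    )


def write_observed_curve(curve: ObservedCmCurve, path) -> None:
    pd.DataFrame(
        {"x": curve.x, "mean_fF": curve.mean, "sd_fF": curve.sd}
    ).to_csv(path, index=False)


def read_points(path) -> np.ndarray:
    """Vesicle or spot coordinate table (x_nm, y_nm[, z_nm])."""
    df = pd.read_csv(path)
    cols = [c for c in ("x_nm", "y_nm", "z_nm") if c in df.columns]
    return df[cols].to_numpy(float)


def write_points(points: np.ndarray, path) -> None:
    points = np.asarray(points, float)
    cols = ["x_nm", "y_nm", "z_nm"][: points.shape[1]]
    pd.DataFrame(points, columns=cols).to_csv(path, index=False)


def read_iv_params(path) -> IVParams:
    with open(path) as fh:
        return IVParams(**json.load(fh))


def read_pool_params(path) -> PoolParams:
    return PoolParams.from_json(path)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
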