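"""Reading and writing motion tables, estimator output, and truth tables.

Canonical interchange format is CSV.  Motion tables have a ``time`` first
column, optional base-pose columns (``base_x/y/z``, quaternion
``base_qw/qx/qy/qz``), one column per actuated DOF named exactly as in the
model, and optional ``<dof>_vel`` / ``<dof>_acc`` columns.  Angles are
radians on disk (``degrees=True`` converts on import).  Missing derivative
columns are filled by Savitzky-Golay smoothing differentiation (window 7,
order 3 by default), which is exact for polynomial trajectories up to the
filter order, including at the edges.

OpenSim-style ``.mot``/``.sto`` tables are accepted read-only: header lines
through ``endheader`` are skipped and columns are whitespace-delimited.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

from .body_model import BodyModel, MotionSample, as_rotation_matrix
from .ddcs_solver import ContactSolution
from .synthetic_gait import TruthRecord

__all__ = [
    "MotionParseError",
    "read_motion",
    "write_motion",
    "motion_to_dataframe",
    "solutions_to_dataframe",
    "write_solutions",
    "read_solutions",
    "truth_to_dataframe",
    "write_truth",
    "write_model",
]

# floats are written with pandas' default shortest-round-trip repr and read
# back with correctly-rounded parsing, so write -> read is lossless

_BASE_POS = ["base_x", "base_y", "base_z"]
_BASE_QUAT = ["base_qw", "base_qx", "base_qy", "base_qz"]
_BASE_VEL = ["base_vx", "base_vy", "base_vz"]
_BASE_ACC = ["base_ax", "base_ay", "base_az"]
_BASE_ANGVEL = ["base_wx", "base_wy", "base_wz"]
_BASE_ANGACC = ["base_alx", "base_aly", "base_alz"]


class MotionParseError(ValueError):
    pass


def motion_to_dataframe(model: BodyModel, samples) -> pd.DataFrame:
    rows = {}
    rows["time"] = [s.t for s in samples]
    for i, c in enumerate(_BASE_POS):
        rows[c] = [s.base_position[i] for s in samples]
    quats = [_matrix_to_quat(as_rotation_matrix(s.base_orientation)) for s in samples]
    for i, c in enumerate(_BASE_QUAT):
        rows[c] = [q[i] for q in quats]
    for cols, attr in ((_BASE_VEL, "base_lin_vel"), (_BASE_ACC, "base_lin_acc"),
                       (_BASE_ANGVEL, "base_ang_vel"), (_BASE_ANGACC, "base_ang_acc")):
        for i, c in enumerate(cols):
            rows[c] = [getattr(s, attr)[i] for s in samples]
    for j, name in enumerate(model.dof_names):
        rows[name] = [s.theta[j] for s in samples]
        rows[f"{name}_vel"] = [s.theta_dot[j] for s in samples]
        rows[f"{name}_acc"] = [s.theta_ddot[j] for s in samples]
    return pd.DataFrame(rows)


def write_motion(path, model: BodyModel, samples) -> None:
    motion_to_dataframe(model, samples).to_csv(path, index=False)


def _matrix_to_quat(R: np.ndarray) -> np.ndarray:
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        return np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                         (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    i = int(np.argmax(np.diag(R)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2
    q = np.empty(4)
    q[0] = (R[k, j] - R[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (R[j, i] + R[i, j]) / s
    q[1 + k] = (R[k, i] + R[i, k]) / s
    return q


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    header_end = None
    for i, line in enumerate(lines[:50]):
        if line.strip().lower() == "endheader":
            header_end = i
            break
    if header_end is not None or path.suffix.lower() in (".mot", ".sto"):
        skip = header_end + 1 if header_end is not None else 0
        df = pd.read_csv(path, skiprows=skip, sep=r"\s+", float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return df


def read_motion(path, model: BodyModel, degrees: bool = False,
                savgol_window: int = 7, savgol_order: int = 3) -> list[MotionSample]:
    """Parse a motion table into MotionSamples for ``model``.

    Unknown columns are warned about (not fatal); missing DOF columns and
    non-monotone time are errors.  Velocity/acceleration columns absent from
    the table are filled by smoothing differentiation.
    """
    df = _read_table(path)
    if "time" not in df.columns:
        raise MotionParseError(f"{path}: first column must be 'time'")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise MotionParseError(f"{path}: non-numeric cell in column {col!r} at line {line}")
    df = df.astype(float).sort_values("time", kind="stable").reset_index(drop=True)
    t = df["time"].to_numpy()
    if len(t) == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise MotionParseError(f"{path}: time stamps must be strictly increasing")

    known = {"time", *_BASE_POS, *_BASE_QUAT, *_BASE_VEL, *_BASE_ACC, *_BASE_ANGVEL, *_BASE_ANGACC}
    for name in model.dof_names:
        if name not in df.columns:
            raise MotionParseError(f"{path}: missing column for DOF {name!r}")
        known |= {name, f"{name}_vel", f"{name}_acc"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}")

    def deriv(y: np.ndarray, order: int) -> np.ndarray:
        if len(t) < 3:
            return np.zeros_like(y)
        dts = np.diff(t)
        if np.allclose(dts, dts[0], rtol=1e-6) and len(y) >= savgol_window:
            return savgol_filter(y, savgol_window, savgol_order, deriv=order,
                                 delta=dts[0], mode="interp")
        d = np.gradient(y, t)
        return d if order == 1 else np.gradient(d, t)

    angles = {}
    vels = {}
    accs = {}
    scale = np.pi / 180.0 if degrees else 1.0
    for name in model.dof_names:
        y = df[name].to_numpy() * scale
        angles[name] = y
        vels[name] = df[f"{name}_vel"].to_numpy() * scale if f"{name}_vel" in df else deriv(y, 1)
        accs[name] = df[f"{name}_acc"].to_numpy() * scale if f"{name}_acc" in df else deriv(y, 2)

    def base_block(cols, fallback_from=None, order=0):
        if all(c in df.columns for c in cols):
            return df[cols].to_numpy()
        if fallback_from is not None:
            return np.column_stack([deriv(fallback_from[:, i], order) for i in range(3)])
        return np.zeros((len(t), 3))

    pos = base_block(_BASE_POS)
    vel = base_block(_BASE_VEL, fallback_from=pos, order=1)
    acc = base_block(_BASE_ACC, fallback_from=pos, order=2)
    angvel = base_block(_BASE_ANGVEL)
    angacc = base_block(_BASE_ANGACC)
    if all(c in df.columns for c in _BASE_QUAT):
        quats = df[_BASE_QUAT].to_numpy()
    else:
        quats = np.tile([1.0, 0, 0, 0], (len(t), 1))

    samples = []
    for i in range(len(t)):
        samples.append(MotionSample(
            t=float(t[i]), base_position=pos[i], base_orientation=quats[i],
            theta=np.array([angles[n][i] for n in model.dof_names]),
            theta_dot=np.array([vels[n][i] for n in model.dof_names]),
            theta_ddot=np.array([accs[n][i] for n in model.dof_names]),
            base_lin_vel=vel[i], base_lin_acc=acc[i],
            base_ang_vel=angvel[i], base_ang_acc=angacc[i],
        ))
    return samples


# ---------------------------------------------------------------------------
# estimator output / truth tables
# ---------------------------------------------------------------------------

def _force_cols(prefix: str, f) -> dict:
    f = np.zeros(3) if f is None else np.asarray(f, float)
    return {f"{prefix}{ax}": v for ax, v in zip("xyz", f)}


def _point_cols(prefix: str, p) -> dict:
    p = np.full(3, np.nan) if p is None else np.asarray(p, float)
    return {f"{prefix}{ax}": v for ax, v in zip("xyz", p)}


def solutions_to_dataframe(sols: list[ContactSolution]) -> pd.DataFrame:
    """One row per sample: time, phase, a, b, k, E, world-frame forces per
    foot, COP coordinates, the dropped X-moment diagnostic, and warnings."""
    rows = []
    for s in sols:
        row = dict(time=s.t, phase=s.phase, a=s.a, b=s.b, k=s.k, E=s.energy)
        row.update(_force_cols("fl", s.f_left))
        row.update(_force_cols("fr", s.f_right))
        row.update(_point_cols("copl_", s.cop_left))
        row.update(_point_cols("copr_", s.cop_right))
        row["dropped_mxd"] = s.dropped_MXD
        row["warnings"] = ";".join(s.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


def write_solutions(path, sols: list[ContactSolution]) -> None:
    solutions_to_dataframe(sols).to_csv(path, index=False)


def read_solutions(path) -> pd.DataFrame:
    return pd.read_csv(path)


def truth_to_dataframe(records: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(time=r.t, phase=r.phase, a=r.a, b=r.b, k=r.k, feasible=r.feasible)
        row.update(_force_cols("fl", r.f_left))
        row.update(_force_cols("fr", r.f_right))
        row.update(_point_cols("copl_", r.cop_left))
        row.update(_point_cols("copr_", r.cop_right))
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(path, records: list[TruthRecord]) -> None:
    truth_to_dataframe(records).to_csv(path, index=False)


def write_model(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
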