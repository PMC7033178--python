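"""Readers and writers for the package's plain-text dialects.

Trajectories: CSV with header ``traj_id,t_s,x_um,y_um,z_um`` plus an optional
``state`` column.  Scattering profiles: two- or three-column text
(q in nm^-1, I, optional sigma), whitespace- or comma-separated, ``#``
comments.  Plate assays and object tables: plain CSV matching the schemas in
:mod:`nanotraffic.formqc` and :mod:`nanotraffic.imaging_quant`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError, require
from .saxs import ScatteringProfile
from .trajmetrics import Trajectory3D

log = logging.getLogger(__name__)

__all__ = [
    "write_trajectories", "read_trajectories",
    "write_profile", "read_profile",
    "write_plate", "read_plate",
    "write_object_table", "read_object_table",
    "write_json_report",
]


def write_trajectories(path, trajectories, state_labels=None) -> None:
    frames = []
    for i, traj in enumerate(trajectories):
        df = pd.DataFrame({
            "traj_id": traj.traj_id,
            "t_s": traj.t,
            "x_um": traj.pos[:, 0],
            "y_um": traj.pos[:, 1],
            "z_um": traj.pos[:, 2],
        })
        if state_labels is not None:
            df["state"] = state_labels[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_trajectories(path) -> tuple[list[Trajectory3D], list | None]:
    """Read a trajectory CSV; returns (trajectories, state_labels_or_None)."""
    df = pd.read_csv(path)
    for col in ("traj_id", "t_s", "x_um", "y_um", "z_um"):
        require(col in df.columns, f"trajectory CSV missing column {col!r}")
    has_state = "state" in df.columns
    trajectories, labels = [], ([] if has_state else None)
    for traj_id, sub in df.groupby("traj_id", sort=False):
        trajectories.append(Trajectory3D(
            traj_id=str(traj_id),
            t=sub["t_s"].to_numpy(float),
            pos=sub[["x_um", "y_um", "z_um"]].to_numpy(float),
        ))
        if has_state:
            labels.append(sub["state"].to_numpy(str))
    return trajectories, labels


def write_profile(path, profile: ScatteringProfile) -> None:
    cols = [profile.q, profile.I]
    header = "q_nm^-1 I"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), fmt="%.9g",
               header=f"{profile.label}\n{header}".strip())


def read_profile(path, q_unit: str | None = None,
                 wavelength_nm: float = 0.154) -> ScatteringProfile:
    """Read a 2/3-column profile; q auto-converted to nm^-1.

    ``q_unit`` may be 'nm^-1' or 'angstrom^-1'; when None the unit is guessed
    from magnitude (max q < 0.7 means angstrom^-1, since the lamellar peak of
    these systems sits near 1 nm^-1 = 0.1 A^-1).  The guess is logged.
    """
    data = np.loadtxt(path, comments="#", delimiter=None if _is_whitespace(path) else ",")
    data = np.atleast_2d(data)
    require(data.shape[1] in (2, 3), "profile file must have 2 or 3 columns")
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] == 3 else None
    if q_unit is None:
        if float(np.max(q)) < 0.7:
            q_unit = "angstrom^-1"
            log.info("read_profile: max q = %.3g < 0.7, assuming angstrom^-1", np.max(q))
        else:
            q_unit = "nm^-1"
    if q_unit == "angstrom^-1":
        q = q * 10.0
    elif q_unit != "nm^-1":
        raise ValidationError(f"unknown q unit {q_unit!r}")
    return ScatteringProfile(q=q, I=I, sigma=sigma, wavelength_nm=wavelength_nm,
                             label=str(Path(path).stem))


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," not in line
    return True


def write_plate(path, wells: pd.DataFrame) -> None:
    wells.to_csv(path, index=False)


def read_plate(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["lysed"] = df["lysed"].astype(bool)
    df["blank"] = df["blank"].astype(bool)
    return df


def write_object_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_object_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
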