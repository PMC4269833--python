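"""File formats: headered CSV tables, TIFF images, JSON results, YAML config.

All tables are UTF-8 CSV with '.' decimal separators and units in the
column headers; floats are written with a fixed repr-stable format so that
re-running a seeded pipeline is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flowstats import VectorField2D
from .model import AxialProfile
from .skew import NucleiRecord

__all__ = [
    "read_profile",
    "write_profile",
    "read_piv_table",
    "write_piv_table",
    "read_nuclei_table",
    "write_nuclei_table",
    "read_image",
    "write_image",
    "write_json",
    "read_config",
    "write_config",
]

FLOAT_FORMAT = "%.10g"


def read_profile(path) -> AxialProfile:
    """AxialProfile from a CSV with columns x_um, value."""
    df = pd.read_csv(path)
    if not {"x_um", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns x_um, value")
    return AxialProfile(df["x_um"].to_numpy(), df["value"].to_numpy())


def write_profile(profile: AxialProfile, path, sem: np.ndarray | None = None) -> None:
    data = {"x_um": profile.x, "value": profile.values}
    if sem is not None:
        data["sem"] = sem
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_piv_table(path) -> list[VectorField2D]:
    """Per-frame vector fields from a PIV CSV.

    Columns: frame, x_um, y_um, vx_um_min, vy_um_min, mask (0/1).
    """
    df = pd.read_csv(path)
    required = {"frame", "x_um", "y_um", "vx_um_min", "vy_um_min", "mask"}
    if not required <= set(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[df[["x_um", "y_um"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-finite positions at rows {list(bad.index[:5])}")
    fields = []
    for frame, grp in df.groupby("frame", sort=True):
        fields.append(
            VectorField2D(
                frame=int(frame),
                points=grp[["x_um", "y_um"]].to_numpy(),
                vectors=grp[["vx_um_min", "vy_um_min"]].to_numpy(),
                mask=grp["mask"].to_numpy().astype(bool),
            )
        )
    return fields


def write_piv_table(fields: list[VectorField2D], path) -> None:
    rows = []
    for f in fields:
        rows.append(
            pd.DataFrame(
                {
                    "frame": f.frame,
                    "x_um": f.points[:, 0],
                    "y_um": f.points[:, 1],
                    "vx_um_min": f.vectors[:, 0],
                    "vy_um_min": f.vectors[:, 1],
                    "mask": f.mask.astype(int),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


_NUCLEI_LABELS = (
    "anterior_pole",
    "posterior_pole",
    "ems_nucleus",
    "initial_a",
    "initial_b",
    "skewed_a",
    "skewed_b",
)


def read_nuclei_table(path, cell: str = "ABa") -> NucleiRecord:
    """NucleiRecord from a labeled 3D point CSV (label, t, x_um, y_um, z_um)."""
    df = pd.read_csv(path)
    required = {"label", "x_um", "y_um", "z_um"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns label, t, x_um, y_um, z_um")
    pos = {}
    for label, grp in df.groupby("label"):
        pos[label] = grp[["x_um", "y_um", "z_um"]].to_numpy()[0]
    missing = [l for l in _NUCLEI_LABELS if l not in pos]
    if missing:
        raise ValueError(f"{path}: missing point labels {missing}")
    return NucleiRecord(
        anterior_pole=pos["anterior_pole"],
        posterior_pole=pos["posterior_pole"],
        ems_nucleus=pos["ems_nucleus"],
        cell=cell,
        initial_axis_points=(pos["initial_a"], pos["initial_b"]),
        skewed_axis_points=(pos["skewed_a"], pos["skewed_b"]),
    )


def write_nuclei_table(record: NucleiRecord, path) -> None:
    pts = {
        "anterior_pole": record.anterior_pole,
        "posterior_pole": record.posterior_pole,
        "ems_nucleus": record.ems_nucleus,
        "initial_a": record.initial_axis_points[0],
        "initial_b": record.initial_axis_points[1],
        "skewed_a": record.skewed_axis_points[0],
        "skewed_b": record.skewed_axis_points[1],
    }
    df = pd.DataFrame(
        {
            "label": list(pts),
            "t": 0,
            "x_um": [p[0] for p in pts.values()],
            "y_um": [p[1] for p in pts.values()],
            "z_um": [p[2] for p in pts.values()],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def write_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
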