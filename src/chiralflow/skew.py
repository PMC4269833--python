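"""Chiral skew angles of ABa/ABp division axes at the 4-cell stage.

An orthonormal right-handed body frame (AP, DV, LR) is built from the
manually identified anterior/posterior pole positions and the EMS nucleus:
the AP unit vector points anterior-to-posterior, the DV unit vector is the
component of the EMS position orthogonal to the AP line (pointing ventrally,
toward EMS), and LR = AP x DV.  Division-axis vectors at the beginning and
end of telophase are then compared as signed angles in the AP-LR plane
(dorsal view), in the DV-LR plane (anterior view), or as the unsigned full
3D angle.

Sign convention: a positive planar angle is clockwise as seen by the named
observer (dorsal view for AP-LR, anterior view for DV-LR), which equals a
right-handed rotation about +DV and +AP respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BodyFrame", "NucleiRecord", "build_body_frame", "skew_angle"]


@dataclass(frozen=True)
class BodyFrame:
    """Right-handed orthonormal embryo axes."""

    ap_hat: np.ndarray
    dv_hat: np.ndarray
    lr_hat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ap_hat", "dv_hat", "lr_hat"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(f"{name} is not unit length")
            object.__setattr__(self, name, v)
        if (
            abs(self.ap_hat @ self.dv_hat) > 1e-10
            or abs(self.ap_hat @ self.lr_hat) > 1e-10
            or abs(self.dv_hat @ self.lr_hat) > 1e-10
        ):
            raise ValueError("axes are not pairwise orthogonal")
        if np.linalg.norm(np.cross(self.ap_hat, self.dv_hat) - self.lr_hat) > 1e-10:
            raise ValueError("frame is not right-handed (AP x DV != LR)")


@dataclass(frozen=True)
class NucleiRecord:
    """Pole, EMS and division-axis nuclei positions for one cell (um).

    ``initial_axis_points`` and ``skewed_axis_points`` are the two nuclei
    positions defining the division axis at the beginning and end of
    telophase.
    """

    anterior_pole: np.ndarray
    posterior_pole: np.ndarray
    ems_nucleus: np.ndarray
    cell: str
    initial_axis_points: tuple[np.ndarray, np.ndarray]
    skewed_axis_points: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        for name in ("anterior_pole", "posterior_pole", "ems_nucleus"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        if np.allclose(self.anterior_pole, self.posterior_pole):
            raise ValueError("pole positions coincide")
        for name in ("initial_axis_points", "skewed_axis_points"):
            a, b = (np.asarray(p, dtype=float) for p in getattr(self, name))
            if np.linalg.norm(b - a) == 0:
                raise ValueError(f"{name} define a zero-length axis")
            object.__setattr__(self, name, (a, b))
        if self.cell not in ("ABa", "ABp"):
            raise ValueError("cell must be 'ABa' or 'ABp'")

    @property
    def initial_vector(self) -> np.ndarray:
        a, b = self.initial_axis_points
        return b - a

    @property
    def skewed_vector(self) -> np.ndarray:
        a, b = self.skewed_axis_points
        return b - a


def build_body_frame(record: NucleiRecord) -> BodyFrame:
    """Orthonormal AP/DV/LR frame from poles and the EMS nucleus.

    DV is the EMS offset from the AP line with its AP component removed
    (Gram-Schmidt); an EMS nucleus lying on the AP line leaves DV undefined.
    """
    ap = record.posterior_pole - record.anterior_pole
    ap_hat = ap / np.linalg.norm(ap)
    w = record.ems_nucleus - record.anterior_pole
    dv = w - (w @ ap_hat) * ap_hat
    dv_norm = np.linalg.norm(dv)
    if dv_norm < 1e-9 * np.linalg.norm(w):
        raise ValueError("EMS nucleus is collinear with the AP axis; DV undefined")
    dv_hat = dv / dv_norm
    lr_hat = np.cross(ap_hat, dv_hat)
    return BodyFrame(ap_hat=ap_hat, dv_hat=dv_hat, lr_hat=lr_hat)


def _project_out(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def skew_angle(
    initial_vec, skewed_vec, frame: BodyFrame, plane: str = "AP-LR"
) -> float:
    """Skew angle (degrees) between division-axis vectors.

    ``plane`` selects the measurement: "AP-LR" (signed, dorsal view),
    "DV-LR" (signed, anterior view) or "full3D" (unsigned).  Positive
    planar angles are clockwise for the named observer.
    """
    a = np.asarray(initial_vec, dtype=float)
    b = np.asarray(skewed_vec, dtype=float)
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise ValueError("axis vectors must be nonzero")
    if plane == "full3D":
        # atan2 form: accurate near 0 and 180 degrees where arccos is not
        return math.degrees(
            math.atan2(np.linalg.norm(np.cross(a, b)), float(a @ b))
        )
    if plane == "AP-LR":
        normal = frame.dv_hat
    elif plane == "DV-LR":
        normal = frame.ap_hat
    else:
        raise ValueError(f"unknown plane {plane!r}")
    ap_ = _project_out(a, normal)
    bp_ = _project_out(b, normal)
    if np.linalg.norm(ap_) < 1e-12 * np.linalg.norm(a) or np.linalg.norm(
        bp_
    ) < 1e-12 * np.linalg.norm(b):
        raise ValueError(f"zero-length projection onto the {plane} plane")
    # right-handed rotation about +normal == clockwise for an observer
    # looking along +normal (dorsal view for DV, anterior view for AP)
    sin_term = normal @ np.cross(ap_, bp_)
    cos_term = ap_ @ bp_
    return math.degrees(math.atan2(sin_term, cos_term))
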