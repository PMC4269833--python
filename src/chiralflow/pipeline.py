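"""End-to-end orchestration of the 1-cell and 4-cell analyses.

The 1-cell workflow mirrors the zygote quantification: per-frame PIV fields
are binned into AP profiles and the counter-rotation velocity v_c, profiles
are hierarchically averaged (time within embryo, then across embryos), and
the thin-film model is fitted to the averaged profiles to yield the
hydrodynamic length and chirality index with Hessian errors.

The 4-cell workflow computes the cleavage-plane-parallel v_c and the
ABa/ABp skew angles, flags outliers by robust z-score (never auto-removed;
exclusion is an explicit config list), and compares conditions with the
rank-sum test.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .fitting import fit_parameters
from .flowstats import (
    BinScheme,
    average_profiles,
    bin_velocity_profile,
    compare_conditions,
    counter_rotation_velocity,
    counter_rotation_velocity_4cell,
)
from .model import SolverConfig
from .skew import build_body_frame, skew_angle

logger = logging.getLogger("chiralflow")

__all__ = ["RunConfig", "run_onecell_analysis", "run_fourcell_analysis", "robust_z"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for a pipeline run; YAML round-trippable."""

    piv_path: str = ""
    intensity_path: str = ""
    nuclei_paths: tuple[str, ...] = ()
    embryo_column: str = "embryo"
    out_dir: str = "out"
    ap_extent: tuple[float, float] = (0.0, 50.0)
    n_bins: int = 18
    stripe_halfwidth: float = 6.5
    y_center: float = 15.0
    n_nodes: int = 201
    interp: str = "pchip"
    alpha_level: float = 0.01
    seed: int = 0
    cleavage_plane_point: tuple[float, float] = (25.0, 15.0)
    cleavage_plane_direction: tuple[float, float] = (0.0, 1.0)
    box_halfwidth: float = 2.5
    excluded: tuple[int, ...] = ()  # explicit manual exclusions (frame ids)

    def bin_scheme(self) -> BinScheme:
        return BinScheme(
            ap_extent=self.ap_extent,
            n_bins=self.n_bins,
            stripe_halfwidth=self.stripe_halfwidth,
            y_center=self.y_center,
        )

    def solver_config(self) -> SolverConfig:
        return SolverConfig(n_nodes=self.n_nodes, interp=self.interp)

    def to_dict(self) -> dict:
        d = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            d[k] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for k, f in cls.__dataclass_fields__.items():
            if k in d:
                v = d[k]
                kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(cfio.read_config(path))

    def to_yaml(self, path) -> None:
        cfio.write_config(self.to_dict(), path)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"missing {what}: {p}")
    return p


def robust_z(values) -> np.ndarray:
    """Outlier score: 0.6745 * (x - median) / MAD (zero MAD -> zeros)."""
    x = np.asarray(values, dtype=float)
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return 0.6745 * (x - med) / mad


def _frame_embryo_map(piv_path, embryo_column: str) -> dict[int, int]:
    df = pd.read_csv(piv_path)
    if embryo_column in df.columns:
        return {
            int(f): int(e)
            for f, e in df.groupby("frame")[embryo_column].first().items()
        }
    return {}


def run_onecell_analysis(config: RunConfig) -> dict:
    """Zygote workflow: profiles, v_c histogram data, model fit.

    Writes vx/vy profile CSVs with SEM, a per-frame v_c CSV, and a fit JSON
    into ``config.out_dir``; returns the report dict.
    """
    piv_path = _require(config.piv_path, "PIV table")
    intensity_path = _require(config.intensity_path, "intensity profile")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "onecell: piv=%s[%s] intensity=%s[%s] seed=%d",
        piv_path, _digest(piv_path), intensity_path, _digest(intensity_path),
        config.seed,
    )

    fields = cfio.read_piv_table(piv_path)
    I = cfio.read_profile(intensity_path).require_intensity()
    scheme = config.bin_scheme()
    embryo_of = _frame_embryo_map(piv_path, config.embryo_column)

    vx_profiles, vy_profiles, embryo_ids, vc_rows = [], [], [], []
    for f in fields:
        vx_profiles.append(bin_velocity_profile(f, scheme, "x"))
        vy_profiles.append(bin_velocity_profile(f, scheme, "y"))
        embryo_ids.append(embryo_of.get(f.frame, 0))
        vc_rows.append((f.frame, embryo_ids[-1], counter_rotation_velocity(f, scheme)))

    vx_stats = average_profiles(vx_profiles, embryo_ids)
    vy_stats = average_profiles(vy_profiles, embryo_ids)
    vc = pd.DataFrame(vc_rows, columns=["frame", "embryo", "vc_um_min"])
    vc["outlier_flag"] = np.abs(robust_z(vc["vc_um_min"])) > 3.5

    from .model import AxialProfile

    vx_mean = AxialProfile(vx_stats.x, vx_stats.mean)
    vy_mean = AxialProfile(vy_stats.x, vy_stats.mean)
    fit = fit_parameters(I, vx_mean, vy_mean, config.solver_config())

    cfio.write_profile(vx_mean, out / "vx_profile.csv", sem=vx_stats.sem)
    cfio.write_profile(vy_mean, out / "vy_profile.csv", sem=vy_stats.sem)
    vc.to_csv(out / "vc_per_frame.csv", index=False, float_format=cfio.FLOAT_FORMAT)
    cfio.write_json(fit.to_dict(), out / "fit.json")

    vc_kept = vc[~vc["frame"].isin(config.excluded)]["vc_um_min"].dropna()
    report = {
        "fit": fit.to_dict(),
        "vc_mean_um_min": float(vc_kept.mean()),
        "vc_sem_um_min": float(vc_kept.sem()) if len(vc_kept) > 1 else math.nan,
        "n_frames": int(len(vc)),
        "n_embryos": int(vx_stats.n_embryos),
        "n_outlier_flags": int(vc["outlier_flag"].sum()),
    }
    cfio.write_json(report, out / "onecell_report.json")
    logger.info("onecell: ell=%.3f c=%.3f rss=%.3g",
                fit.params.ell, fit.params.c, fit.rss)
    return report


def run_fourcell_analysis(config: RunConfig) -> dict:
    """4-cell workflow: cleavage-plane v_c, skew angles, outlier flags."""
    piv_path = _require(config.piv_path, "PIV table")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("fourcell: piv=%s[%s] seed=%d", piv_path, _digest(piv_path), config.seed)

    fields = cfio.read_piv_table(piv_path)
    vc_rows = []
    for f in fields:
        vc_rows.append(
            (
                f.frame,
                counter_rotation_velocity_4cell(
                    f,
                    config.cleavage_plane_point,
                    config.cleavage_plane_direction,
                    config.box_halfwidth,
                ),
            )
        )
    vc = pd.DataFrame(vc_rows, columns=["frame", "vc_um_min"])
    vc["outlier_flag"] = np.abs(robust_z(vc["vc_um_min"])) > 3.5
    vc.to_csv(out / "vc_4cell_per_frame.csv", index=False, float_format=cfio.FLOAT_FORMAT)

    angles = []
    for path in config.nuclei_paths:
        record = cfio.read_nuclei_table(_require(path, "nuclei table"))
        frame = build_body_frame(record)
        angles.append(
            {
                "source": str(path),
                "cell": record.cell,
                "ap_lr_deg": skew_angle(
                    record.initial_vector, record.skewed_vector, frame, "AP-LR"
                ),
                "dv_lr_deg": skew_angle(
                    record.initial_vector, record.skewed_vector, frame, "DV-LR"
                ),
                "full3d_deg": skew_angle(
                    record.initial_vector, record.skewed_vector, frame, "full3D"
                ),
            }
        )
    if angles:
        pd.DataFrame(angles).to_csv(
            out / "skew_angles.csv", index=False, float_format=cfio.FLOAT_FORMAT
        )

    vc_kept = vc[~vc["frame"].isin(config.excluded)]["vc_um_min"].dropna()
    ap_lr = [a["ap_lr_deg"] for a in angles]
    report = {
        "vc_mean_um_min": float(vc_kept.mean()) if len(vc_kept) else math.nan,
        "vc_sem_um_min": float(vc_kept.sem()) if len(vc_kept) > 1 else math.nan,
        "n_frames": int(len(vc)),
        "n_outlier_flags": int(vc["outlier_flag"].sum()),
        "skew_ap_lr_mean_deg": float(np.mean(ap_lr)) if ap_lr else math.nan,
        "skew_ap_lr_median_deg": float(np.median(ap_lr)) if ap_lr else math.nan,
        "skew_ap_lr_sem_deg": (
            float(np.std(ap_lr, ddof=1) / math.sqrt(len(ap_lr)))
            if len(ap_lr) > 1
            else math.nan
        ),
        "n_videos": len(angles),
    }
    cfio.write_json(report, out / "fourcell_report.json")
    return report


def compare_condition_files(path_a, path_b, alpha_level: float = 0.01) -> dict:
    """Rank-sum comparison of two per-frame v_c CSVs (column vc_um_min)."""
    a = pd.read_csv(path_a)["vc_um_min"].dropna().to_numpy()
    b = pd.read_csv(path_b)["vc_um_min"].dropna().to_numpy()
    return compare_conditions(a, b, alpha_level).to_dict()
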