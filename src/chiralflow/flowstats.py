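"""Summary statistics of PIV-derived cortical flow fields.

Per-frame 2D velocity fields are reduced to AP-binned profiles (18 equal
bins along the anteroposterior axis, restricted to a ~13 um stripe around
the embryo midline), to the chiral counter-rotation velocity

    v_c = <vy>_posterior - <vy>_anterior

(anterior = bins 3-6, posterior = bins 13-16, 1-based), and to its 4-cell
variant measured parallel to the ABa cleavage plane.  Conditions are
compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import AxialProfile

__all__ = [
    "VectorField2D",
    "BinScheme",
    "ProfileStats",
    "ComparisonReport",
    "bin_velocity_profile",
    "average_profiles",
    "counter_rotation_velocity",
    "counter_rotation_velocity_4cell",
    "half_intensity_difference",
    "compare_conditions",
]


@dataclass(frozen=True)
class VectorField2D:
    """One frame of PIV output: positions (um), velocities (um/min), mask."""

    frame: int
    points: np.ndarray  # (N, 2)
    vectors: np.ndarray  # (N, 2)
    mask: np.ndarray  # (N,) bool, True = include

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        m = np.asarray(self.mask, dtype=bool)
        if p.shape != v.shape or p.shape[1] != 2 or len(m) != len(p):
            raise ValueError("points, vectors and mask shapes are inconsistent")
        if not np.all(np.isfinite(v[m])):
            raise ValueError("non-finite velocity at a masked-in point")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class BinScheme:
    """AP binning geometry.

    Bins are 1-based to match the anterior (3-6) / posterior (13-16)
    region definitions.  The stripe is centred on ``y_center`` with
    half-width ``stripe_halfwidth`` (13 um total by default).
    """

    ap_extent: tuple[float, float]
    n_bins: int = 18
    stripe_halfwidth: float = 6.5
    y_center: float = 0.0
    anterior_bins: tuple[int, ...] = (3, 4, 5, 6)
    posterior_bins: tuple[int, ...] = (13, 14, 15, 16)

    def __post_init__(self) -> None:
        if self.ap_extent[1] <= self.ap_extent[0]:
            raise ValueError("ap_extent must be an increasing interval")
        if set(self.anterior_bins) & set(self.posterior_bins):
            raise ValueError("anterior and posterior bin sets overlap")
        for b in (*self.anterior_bins, *self.posterior_bins):
            if not 1 <= b <= self.n_bins:
                raise ValueError(f"bin index {b} outside 1..{self.n_bins}")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.ap_extent[0], self.ap_extent[1], self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


def _stripe_points(field: VectorField2D, scheme: BinScheme) -> np.ndarray:
    y = field.points[:, 1]
    return field.mask & (np.abs(y - scheme.y_center) <= scheme.stripe_halfwidth)


def bin_velocity_profile(
    field: VectorField2D, scheme: BinScheme, component: str
) -> AxialProfile:
    """Spatial mean of one velocity component per AP bin, stripe-restricted.

    Empty bins yield NaN, which downstream averages treat as missing.
    """
    comp = {"x": 0, "y": 1}[component]
    keep = _stripe_points(field, scheme)
    x = field.points[keep, 0]
    v = field.vectors[keep, comp]
    edges = scheme.edges
    # right-closed last bin so the posterior edge point is not dropped
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, scheme.n_bins - 1)
    inside = (x >= edges[0]) & (x <= edges[-1])
    out = np.full(scheme.n_bins, np.nan)
    for b in range(scheme.n_bins):
        sel = inside & (idx == b)
        if np.any(sel):
            out[b] = v[sel].mean()
    return AxialProfile(scheme.centers, out)


@dataclass(frozen=True)
class ProfileStats:
    """Across-embryo mean profile with per-bin SEM."""

    x: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_embryos: int


def average_profiles(per_frame: list[AxialProfile], embryo_ids) -> ProfileStats:
    """Embryo-first hierarchical average of per-frame binned profiles.

    Frames are time-averaged within each embryo, then the per-embryo means
    are averaged without weighting by frame count; the SEM is computed
    across embryos per bin (NaN for a single embryo).
    """
    embryo_ids = list(embryo_ids)
    if len(embryo_ids) != len(per_frame):
        raise ValueError("one embryo id per frame required")
    x = per_frame[0].x
    for p in per_frame[1:]:
        if not np.allclose(p.x, x):
            raise ValueError("all profiles must share one bin scheme")
    by_embryo = {}
    for eid, prof in zip(embryo_ids, per_frame):
        by_embryo.setdefault(eid, []).append(prof.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        embryo_means = np.array(
            [np.nanmean(np.vstack(vals), axis=0) for vals in by_embryo.values()]
        )
        mean = np.nanmean(embryo_means, axis=0)
        n = embryo_means.shape[0]
        if n > 1:
            sem = np.nanstd(embryo_means, axis=0, ddof=1) / math.sqrt(n)
        else:
            sem = np.full_like(mean, np.nan)
    return ProfileStats(x=x, mean=mean, sem=sem, n_embryos=n)


def _region_mean(profile: AxialProfile, bins_1based) -> float:
    vals = profile.values[np.asarray(bins_1based) - 1]
    if np.all(np.isnan(vals)):
        return math.nan
    return float(np.nanmean(vals))


def counter_rotation_velocity(field: VectorField2D, scheme: BinScheme) -> float:
    """Chiral counter-rotation velocity v_c of one frame (um/min).

    Mean y-velocity over the posterior bins minus the anterior bins; NaN
    (frame undefined) if either region is empty.
    """
    prof = bin_velocity_profile(field, scheme, "y")
    post = _region_mean(prof, scheme.posterior_bins)
    ant = _region_mean(prof, scheme.anterior_bins)
    if math.isnan(post) or math.isnan(ant):
        warnings.warn("empty anterior or posterior region; v_c undefined", stacklevel=2)
        return math.nan
    return post - ant


def counter_rotation_velocity_4cell(
    field: VectorField2D,
    plane_point,
    plane_direction,
    box_halfwidth: float = 2.5,
) -> float:
    """Counter-rotation velocity across a cleavage plane (4-cell stage).

    The velocity component parallel to the cleavage plane is averaged in a
    band of width ``2 * box_halfwidth`` on each side of the plane and
    differenced left-minus-right.  "Left" is the side to the left when
    facing along ``plane_direction`` (the +90 degree normal).
    """
    p0 = np.asarray(plane_point, dtype=float)
    d = np.asarray(plane_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("plane direction must be nonzero")
    d = d / norm
    n = np.array([-d[1], d[0]])  # left normal
    pts = field.points[field.mask]
    vec = field.vectors[field.mask]
    s = (pts - p0) @ n  # signed distance, >0 on the left
    v_par = vec @ d
    width = 2.0 * box_halfwidth
    left = (s > 0) & (s <= width)
    right = (s < 0) & (s >= -width)
    if not (np.any(left) and np.any(right)):
        warnings.warn("empty box on one side of the cleavage plane", stacklevel=2)
        return math.nan
    return float(v_par[left].mean() - v_par[right].mean())


def half_intensity_difference(
    image: np.ndarray, mask: np.ndarray, split: str = "AP-halves"
) -> float:
    """Mean-intensity difference between two embryo halves (a.u.).

    ``"AP-halves"``: posterior minus anterior, split at the AP midpoint of
    the masked region (image columns = AP axis).  ``"top-bottom-posterior"``:
    top minus bottom within the posterior half, probing azimuthal symmetry
    of the myosin distribution.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    rows, cols = np.nonzero(mask)
    if len(cols) == 0:
        raise ValueError("empty mask")
    x_mid = 0.5 * (cols.min() + cols.max())
    col_grid = np.arange(image.shape[1])[None, :]
    posterior = mask & (col_grid > x_mid)
    anterior = mask & (col_grid <= x_mid)
    if split == "AP-halves":
        region1, region2 = posterior, anterior
    elif split == "top-bottom-posterior":
        prow, _ = np.nonzero(posterior)
        if len(prow) == 0:
            raise ValueError("empty posterior region")
        y_mid = 0.5 * (prow.min() + prow.max())
        row_grid = np.arange(image.shape[0])[:, None]
        region1 = posterior & (row_grid < y_mid)  # top (low row index)
        region2 = posterior & (row_grid >= y_mid)
    else:
        raise ValueError(f"unknown split {split!r}")
    if not (np.any(region1) and np.any(region2)):
        raise ValueError("a split region is empty")
    return float(image[region1].mean() - image[region2].mean())


@dataclass(frozen=True)
class ComparisonReport:
    p_value: float
    significant: bool
    alpha_level: float
    mean_a: float
    mean_b: float
    ci_halfwidth_a: float
    ci_halfwidth_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_conditions(
    sample_a, sample_b, alpha_level: float = 0.01
) -> ComparisonReport:
    """Two-sided Wilcoxon rank-sum comparison of two v_c (or angle) samples.

    Means are reported with z * SEM half-widths at the matching confidence
    (2.576 x SEM at the 0.01 level, 1.96 x SEM at 0.05).  Samples in which
    every value is tied short-circuit to p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
    z = float(stats.norm.ppf(1 - alpha_level / 2))

    def _ci(x):
        if len(x) < 2:
            return math.nan
        return z * float(np.std(x, ddof=1)) / math.sqrt(len(x))

    return ComparisonReport(
        p_value=p,
        significant=bool(p < alpha_level),
        alpha_level=alpha_level,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ci_halfwidth_a=_ci(a),
        ci_halfwidth_b=_ci(b),
        n_a=len(a),
        n_b=len(b),
    )
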