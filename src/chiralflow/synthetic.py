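"""Synthetic inputs with known ground truth for every analysis stage.

Emulates the statistical structure of the study's measurements: smooth
anterior-high sigmoid myosin gradients (1-cell stage) and Gaussian stripe
profiles (cleavage furrow), velocity profiles and 2D PIV-like vector fields
obeying the thin-film model with known (ell, alpha, beta) plus i.i.d.
Gaussian noise, intensity images with a prescribed isotropic exponential
correlation length, and nuclei configurations rotated by prescribed skew
angles about known body axes.

Every generator is a pure function of a :class:`SyntheticSpec` (and an
optional externally supplied generator), so a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .flowstats import BinScheme, VectorField2D
from .model import (
    AxialProfile,
    ModelParams,
    SolverConfig,
    forward_model,
    solve_axial_flow,
    solve_chiral_flow,
)
from .skew import NucleiRecord, build_body_frame

__all__ = [
    "SyntheticSpec",
    "make_intensity_profile",
    "make_velocity_profiles",
    "make_vector_field",
    "make_correlated_image",
    "make_skewed_nuclei",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth, geometry, noise levels and seed for all generators.

    Defaults describe a typical zygote: a 50 x 30 um cortical footprint,
    18 AP bins, an anterior-high myosin gradient, per-sample velocity
    noise of 0.5 um/min, 0.1 um pixels for images.  ``truth`` mirrors the
    measured non-RNAi regime (ell = 16 um, c = 0.58).
    """

    truth: ModelParams = field(
        default_factory=lambda: ModelParams(ell=16.0, alpha=10.0, beta=5.8)
    )
    embryo_length: float = 50.0
    embryo_width: float = 30.0
    n_bins: int = 18
    profile_family: str = "sigmoid"
    profile_base: float = 0.5
    profile_amplitude: float = 1.0
    profile_steepness: float = 0.2  # 1/um; 0 gives a constant profile
    # the anterior myosin-rich domain extends to ~60% of egg length before
    # pseudocleavage, so the gradient zone sits in the mid-to-posterior half
    profile_midpoint_frac: float = 0.6
    stripe_sigma: float = 5.0  # um, gaussian-stripe family
    noise_sd: float = 0.5  # um/min per velocity sample
    n_frames: int = 10
    n_embryos: int = 5
    seed: int = 0
    grid_spacing: float = 1.0  # um between PIV vectors
    pixel_size: float = 0.1  # um/px for images
    image_shape: tuple[int, int] = (256, 256)
    corr_length: float = 2.0  # um, imposed image correlation length
    skew_truth_deg: float = 20.0
    skew_axis: str = "dv"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def bin_scheme(self) -> BinScheme:
        return BinScheme(
            ap_extent=(0.0, self.embryo_length),
            n_bins=self.n_bins,
            y_center=self.embryo_width / 2.0,
        )


def make_intensity_profile(spec: SyntheticSpec) -> AxialProfile:
    """Noise-free myosin intensity on the AP bin centres.

    "sigmoid": anterior-high logistic gradient, monotone decreasing along
    AP; zero steepness degenerates to a constant.  "gaussian-stripe": a
    bump centred mid-embryo emulating a cleavage furrow.
    """
    x = spec.bin_scheme().centers
    if spec.profile_family == "sigmoid":
        x0 = spec.profile_midpoint_frac * spec.embryo_length
        vals = spec.profile_base + spec.profile_amplitude / (
            1.0 + np.exp(spec.profile_steepness * (x - x0))
        )
    elif spec.profile_family == "gaussian-stripe":
        x0 = spec.embryo_length / 2.0
        vals = spec.profile_base + spec.profile_amplitude * np.exp(
            -0.5 * ((x - x0) / spec.stripe_sigma) ** 2
        )
    else:
        raise ValueError(f"unknown profile family {spec.profile_family!r}")
    return AxialProfile(x, vals)


def make_velocity_profiles(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    cfg: SolverConfig | None = None,
):
    """Intensity plus noisy per-frame (vx, vy) profiles from the model.

    The noiseless expectation of every frame equals the forward-model
    solution with zero boundary velocities; frame noise is i.i.d. Gaussian
    per bin with SD ``spec.noise_sd``.

    Returns ``(I, frames)`` with ``frames`` a list of ``(vx, vy)`` pairs.
    """
    rng = spec.rng() if rng is None else rng
    cfg = cfg or SolverConfig()
    I = make_intensity_profile(spec)
    vx0, vy0 = forward_model(I, spec.truth, cfg)
    frames = []
    for _ in range(spec.n_frames):
        nx = rng.normal(0.0, spec.noise_sd, I.n) if spec.noise_sd > 0 else 0.0
        ny = rng.normal(0.0, spec.noise_sd, I.n) if spec.noise_sd > 0 else 0.0
        frames.append(
            (AxialProfile(I.x, vx0.values + nx), AxialProfile(I.x, vy0.values + ny))
        )
    return I, frames


def make_vector_field(
    spec: SyntheticSpec,
    frame: int = 0,
    rng: np.random.Generator | None = None,
    vy_offset_anterior: float = 0.0,
    vy_offset_posterior: float = 0.0,
) -> VectorField2D:
    """One PIV-like frame: the 1D model flow tiled across the embryo width.

    Vectors sit on a regular ``grid_spacing`` lattice over the embryo
    footprint; each inherits (vx(x), vy(x)) from a fine-grid model solution
    plus i.i.d. Gaussian noise.  Optional uniform vy offsets over the
    anterior/posterior bin regions support constructed counter-rotation
    tests.
    """
    rng = spec.rng() if rng is None else rng
    I = make_intensity_profile(spec)
    cfg = SolverConfig(n_nodes=1001)
    vx_sol = solve_axial_flow(I, spec.truth, cfg)
    vy_sol = solve_chiral_flow(I, spec.truth, cfg)
    xs = np.arange(0.0, spec.embryo_length + 1e-9, spec.grid_spacing)
    ys = np.arange(0.0, spec.embryo_width + 1e-9, spec.grid_spacing)
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    vx = np.interp(pts[:, 0], vx_sol.x, vx_sol.values)
    vy = np.interp(pts[:, 0], vy_sol.x, vy_sol.values)
    scheme = spec.bin_scheme()
    edges = scheme.edges
    if vy_offset_anterior != 0.0:
        lo = edges[min(scheme.anterior_bins) - 1]
        hi = edges[max(scheme.anterior_bins)]
        vy = np.where((pts[:, 0] >= lo) & (pts[:, 0] <= hi), vy + vy_offset_anterior, vy)
    if vy_offset_posterior != 0.0:
        lo = edges[min(scheme.posterior_bins) - 1]
        hi = edges[max(scheme.posterior_bins)]
        vy = np.where((pts[:, 0] >= lo) & (pts[:, 0] <= hi), vy + vy_offset_posterior, vy)
    if spec.noise_sd > 0:
        vx = vx + rng.normal(0.0, spec.noise_sd, len(pts))
        vy = vy + rng.normal(0.0, spec.noise_sd, len(pts))
    vectors = np.column_stack([vx, vy])
    return VectorField2D(
        frame=frame, points=pts, vectors=vectors, mask=np.ones(len(pts), dtype=bool)
    )


def make_correlated_image(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Gaussian random field with isotropic exponential spatial correlation.

    Synthesized spectrally: white Fourier noise shaped by the square root
    of the 2D power spectrum of ``exp(-r / corr_length)``, which is
    proportional to ``(1 + (k * corr_length)^2)^(-3/2)``.  The field is
    scaled by its theoretical (ensemble) standard deviation rather than the
    per-image sample value, so realization-to-realization fluctuations of
    the image mean and variance are preserved, and offset to a positive
    mean so it resembles a fluorescence image.
    """
    rng = spec.rng() if rng is None else rng
    ny, nx = spec.image_shape
    ky = np.fft.fftfreq(ny, d=spec.pixel_size) * 2 * np.pi
    kx = np.fft.fftfreq(nx, d=spec.pixel_size) * 2 * np.pi
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    amp = (1.0 + k2 * spec.corr_length**2) ** (-0.75)
    noise = rng.normal(size=(ny, nx))
    field_k = np.fft.fft2(noise) * amp
    img = np.fft.ifft2(field_k).real
    img /= np.sqrt(np.mean(amp**2))  # theoretical per-pixel SD of the field
    return img + 5.0


_AXES = {"dv": "dv_hat", "ap": "ap_hat", "lr": "lr_hat"}


def make_skewed_nuclei(
    spec: SyntheticSpec,
    rotations: list[tuple[str, float]] | None = None,
    cell: str = "ABa",
) -> NucleiRecord:
    """Nuclei configuration whose skew angles are known by construction.

    The reference embryo has poles on the x-axis and EMS ventrally offset,
    so the body frame is the lab frame.  The initial division axis is
    (AP + LR)/sqrt(2) — nonzero projections in both measurement planes —
    and the skewed axis applies right-handed rotations about the named body
    axes ("dv", "ap", "lr"), defaulting to ``skew_truth_deg`` about
    ``spec.skew_axis``.  A positive angle about DV is clockwise viewed
    dorsally.
    """
    L = spec.embryo_length
    anterior = np.array([0.0, 0.0, 0.0])
    posterior = np.array([L, 0.0, 0.0])
    ems = np.array([L / 2.0, L / 4.0, 0.0])
    center = np.array([L / 4.0, 0.0, 0.0])  # ABa sits anteriorly
    frame_axes = {
        "ap": np.array([1.0, 0.0, 0.0]),
        "dv": np.array([0.0, 1.0, 0.0]),
        "lr": np.array([0.0, 0.0, 1.0]),
    }
    initial = (frame_axes["ap"] + frame_axes["lr"]) / np.sqrt(2.0)
    if rotations is None:
        rotations = [(spec.skew_axis, spec.skew_truth_deg)]
    skewed = initial.copy()
    for axis_name, deg in rotations:
        axis = frame_axes[axis_name]
        skewed = Rotation.from_rotvec(np.radians(deg) * axis).apply(skewed)
    half = 5.0  # um half-separation of the nuclei pair
    record = NucleiRecord(
        anterior_pole=anterior,
        posterior_pole=posterior,
        ems_nucleus=ems,
        cell=cell,
        initial_axis_points=(center - half * initial, center + half * initial),
        skewed_axis_points=(center - half * skewed, center + half * skewed),
    )
    # generator output must satisfy the consuming module's invariants
    build_body_frame(record)
    return record
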