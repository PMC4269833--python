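# Methods

## Model

The cortex is described as a thin film of an active chiral fluid on a
one-dimensional anteroposterior (AP) domain under azimuthal symmetry. The
axial and chiral velocity components obey screened force/torque balances

    ell * vx'' - vx/ell = -d/dx(alpha * I(x))
    (ell/2) * vy'' - vy/ell = -d/dx(beta * I(x))

where `I(x)` is the myosin fluorescence intensity, `alpha` and `beta`
convert intensity into active tension and active torque density (both
carried in velocity units, i.e. the physical stresses divided by the
friction coefficient), and `ell` is the hydrodynamic length. Because the
friction and viscosity never appear separately in these reduced equations,
(`ell`, `alpha`, `beta`) are the complete identifiable parameter set; the
chirality index is `c = beta/alpha`.

Two printed-form subtleties are resolved as follows.

- **Viscous prefactor asymmetry.** The chiral equation carries a factor
  1/2 on the viscous term while the axial one does not; we keep this
  asymmetry exactly as stated rather than symmetrizing. Its observable
  consequence is that the far field of a localized source decays as
  `exp(-x/ell)` axially but `exp(-x*sqrt(2)/ell)` chirally, which the test
  suite verifies by log-slope fits.
- **Sign of the driving term.** Stated one way, the force balance sends
  flow away from regions of high tension; stated the other, toward them.
  A contractile cortex pulls material toward high myosin — a stripe of
  high activity (a cleavage furrow) draws flow inward from both sides —
  so the driving-force convention (`-d/dx(alpha I)` on the right-hand
  side) is used. With it, all the qualitative statements of the theory
  hold with positive `alpha` and `beta`: inward stripe flow, antisymmetric
  counter-rotating `vy` around a stripe, and negative counter-rotation
  velocity `v_c` for an anterior-high gradient with `c > 0`. The opposite
  convention merely flips the signs of the fitted `alpha` and `beta`
  (leaving `c` and all magnitudes unchanged).

### Discretization

Second-order central differences on a uniform grid (201 nodes by default)
spanning exactly the extent of the input profile; Dirichlet boundary
values at the two ends; banded (tridiagonal) solve. The source derivative
is evaluated by central differences with second-order one-sided stencils
at the boundaries. Measured 18-bin intensity profiles are resampled onto
the solver grid with shape-preserving monotone cubic (PCHIP) interpolation
— linear is available — because an overshooting interpolant would
fabricate tension gradients between bins. Self-convergence (201 vs 2001
nodes) is below 0.1% relative L2 on step profiles, and the solution
matches an independent Green's-function quadrature oracle to ~0.2% on a
narrow-Gaussian source.

Boundary conditions follow the measurement convention: the two extreme
points of the observed velocity profile, used raw (no smoothing); zero for
pure simulation.

## Parameter fitting

For fixed `ell` the model velocity is linear in `alpha` (axial) and `beta`
(chiral), and the boundary-value contribution is independent of both, so
the least-squares problem is profiled: an outer bounded 1D minimization
over `ell` (coarse log-spaced scan over [grid spacing, 10 x domain
length], then Brent refinement) with exact closed-form inner solutions for
`alpha` and `beta`. This replaces a fragile 3D nonlinear fit with a robust
1D search. Endpoint samples are excluded from the residual since they are
imposed as boundary conditions. Residuals of `vx` and `vy` are weighted
equally.

Standard errors come from the Hessian of half the residual sum of squares
at the optimum, computed by central finite differences with a relative
step of 1e-3 (large enough that solver-level numerical noise, ~1e-10
relative, does not contaminate the second differences; halving the step
changes well-conditioned standard errors by <1%). The covariance is
`s^2 * H^-1` with `s^2 = rss/(n_obs - 3)`; the error on `c = beta/alpha`
follows by first-order propagation including the alpha-beta covariance. A
non-positive-definite Hessian (flat direction, e.g. vanishing intensity)
yields NaN errors with a warning. Confidence half-widths elsewhere in the
package use the normal approximation (2.576 x SEM at 99%, 1.96 x SEM at
95%).

Monte-Carlo calibration (100 replicates, 10% velocity noise) shows the
mean fitted `c` within 0.01-0.02 of truth and the reported standard error
within a factor ~1.5 of the empirical spread. Individual noisy single-
profile fits can wander along the poorly constrained `ell` direction; the
pipeline therefore fits time- and embryo-averaged profiles, as the
measurement protocol prescribes.

## Flow statistics

2D PIV fields are reduced to 18 equal AP bins restricted to a 13 µm-wide
stripe centred on the embryo midline (the centring is a package choice;
only the stripe width is prescribed). Bin indices are 1-based so the
anterior region is bins 3–6 and the posterior region bins 13–16. Profile
averaging is hierarchical — time within embryo first, then an unweighted
mean across embryos, SEM across embryos — whereas `v_c` histograms pool
frames across embryos; these two deliberately different procedures match
the two measurement conventions. Empty bins propagate as missing values.

The 4-cell variant projects velocities onto the cleavage-plane direction
and differences the means over 5 µm-wide bands on the left and right of
the plane ("left" = left when facing along the plane direction); it is
rotation-invariant by construction.

Condition comparisons use the two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`, exact for small tie-free samples); fully tied
samples short-circuit to p = 1. Outliers are never removed automatically:
frames are flagged at robust z (0.6745·(x−median)/MAD) above 3.5 and
excluded only through an explicit configuration list, because the study's
exclusions were qualitative judgements (sideways polarization, whole-body
rotation) that cannot be automated faithfully.

## Skew angles

The body frame is built from the anterior→posterior pole vector, the EMS
nucleus offset orthogonalized against it (Gram–Schmidt; the foot of the
perpendicular is the reference point), and `lr = ap × dv`; the frame is
right-handed and `dv` points ventrally, toward EMS. Planar skew angles are
signed: positive = clockwise for an observer looking along +dv (dorsal
view, AP–LR plane) or along +ap (anterior view, DV–LR plane), which equals
a right-handed rotation about the respective axis. The printed magnitudes
of the study carry no sign convention; ours is a documented choice with a
configurable flip (negate the returned angle). The 3D angle is unsigned
and computed in atan2 form for accuracy near 0°. All angles are invariant
under global rigid motion and flip sign under mirror reflection through
the AP–DV plane — the chirality-detector property.

## Foci size

The spatial autocorrelation of a myosin image (or a ~27 × 13 µm anterior
stripe ROI) is computed by zero-padded FFT, divided by the per-lag overlap
count (unbiased estimator), normalized at zero lag, and radially averaged
with one-pixel-wide bins out to half the window size. The foci size is the
decay length of a least-squares fit of `A·exp(-r/λ)` over lags 0.5–5 µm;
the lower bound excludes the zero-lag camera-noise spike.

Subtracting a single window's own sample mean removes genuine
low-frequency signal and biases the apparent decay length downward by
O((λ/L)²) terms — severe when λ approaches the window size (about −25% for
λ = 4 µm on a 25.6 µm window). `stack_autocorrelation` therefore pools the
mean intensity across the frames of a movie, averages the unnormalized
per-frame autocovariances, and normalizes once; with the pooled mean the
bias shrinks with stack length, and recovery of imposed correlation
lengths of 1, 2 and 4 µm is within 10% (stacks of 32, 32 and 96 frames of
256² px at 0.1 µm/px). Per-frame estimates remain available and are
ensemble-averaged embryo-first, matching the early-flow-window protocol.

## Synthetic data

The generators emulate the statistical structure of the study's inputs:

- **Myosin profiles.** An anterior-high sigmoid with midpoint at 60% of
  egg length (the anterior myosin domain extends to roughly 60% before
  pseudocleavage, so the gradient zone sits in the mid-to-posterior half)
  and steepness 0.2 µm⁻¹; or a Gaussian stripe (σ = 5 µm) centred
  mid-embryo emulating a cleavage furrow. Embryo length 50 µm, width
  30 µm.
- **Velocity data.** Forward-model solutions with ground-truth parameters
  (default ℓ = 16 µm, c = 0.58 — the measured non-RNAi regime) plus
  i.i.d. Gaussian noise per bin/vector, 0.5 µm/min by default
  (SEM-bar-scale). 2D fields tile the 1D solution across the width on a
  1 µm lattice; region-wise `vy` offsets can be injected for constructed
  counter-rotation tests.
- **Images.** Gaussian random fields synthesized spectrally with the
  exact 2D power spectrum of an exponential correlation function,
  `(1 + k²λ²)^(-3/2)`, scaled by the theoretical (ensemble) standard
  deviation so that per-realization mean/variance fluctuations are
  preserved, then offset to a positive mean.
- **Nuclei.** A reference embryo with poles on the x-axis and EMS offset
  ventrally; the initial division axis is `(ap + lr)/√2` (nonzero
  projection in both measurement planes) and the skewed axis applies
  prescribed rotations about named body axes.

All generators are pure functions of a spec containing the seed;
regeneration is byte-identical.

What passing tests on these data do **not** show: the generators contain
no PIV estimation error structure (spatially correlated noise, window
artifacts), no embryo shape or curvature, no photobleaching or
shot-noise statistics in images, and no biological variability between
embryos beyond injected noise. Results on real recordings depend on those
factors; the tests validate the estimators and the model pipeline, not the
microscopy.

## Problem sizes

Defaults throughout were chosen so the full suite and the verification
script run in well under a minute each on one core: 201-node solves for
fitting (2001–4001 for oracle and screening checks), 100-replicate noise
studies, and image stacks of 32–96 frames at 256² px. All are package
choices and scale up by configuration.

## Known limitations

- `ell` is weakly identified from a single noisy 18-bin profile; fits are
  intended for averaged profiles.
- The chiral screening length ℓ/√2 is inherited from the printed factor
  1/2; if that factor were a typographical artefact the chiral decay
  would equal the axial one. We follow the printed form.
- The foci-size estimator assumes an isotropic, approximately exponential
  correlation structure; strongly anisotropic textures violate the radial
  averaging.
- The 4-cell `v_c` assumes a straight cleavage plane within the analysis
  boxes.
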