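# chiralflow

Quantification and modelling of chiral actomyosin cortical flow in the early
*C. elegans* embryo.

The actomyosin cortex is a thin contractile layer in which myosin motors
generate not only an active tension *T* but also an active torque density
*τ*. Treating the cortex as a thin film of an active chiral fluid screened
by friction with the membrane and cytoplasm, and assuming both stresses are
proportional to the myosin fluorescence intensity *I(x)* along the
anteroposterior (AP) axis (*T = αI*, *τ = βI*), the flow components along
(*v<sub>x</sub>*) and orthogonal to (*v<sub>y</sub>*) the AP axis obey

```
ℓ ∂²x vx − vx/ℓ = −∂x(αI)
(ℓ/2) ∂²x vy − vy/ℓ = −∂x(βI)
```

with ℓ the hydrodynamic length over which flow is screened. Tension
gradients drive flow along the AP axis toward regions of high myosin;
torque-density gradients drive *chiral* flow orthogonal to the gradient.
The dimensionless chirality index **c = β/α = τ/T** measures how much motor
activity is converted into torque rather than tension. Note the chiral
component's shorter screening length ℓ/√2.

The package provides, as library functions and a `chiralflow` CLI:

- **model** — a finite-difference two-point boundary-value solver for the
  equations above, with Dirichlet boundary velocities taken from the two
  extreme points of a measured profile;
- **fitting** — least-squares estimation of (ℓ, α, β) from binned PIV
  velocity profiles, exploiting linearity in (α, β) to reduce the problem
  to a 1D search over ℓ, with standard errors from the Hessian of the
  residual;
- **flowstats** — 18-bin AP velocity profiles from 2D PIV fields, the
  chiral counter-rotation velocity `v_c = ⟨vy⟩posterior − ⟨vy⟩anterior`
  (plus the 4-cell cleavage-plane variant), azimuthal-symmetry intensity
  differences, and Wilcoxon rank-sum condition comparisons;
- **skew** — signed ABa/ABp division-axis skew angles in the AP–LR and
  DV–LR planes and the full 3D angle, from pole/EMS/nuclei coordinates;
- **foci** — myosin foci size as the exponential decay length of the
  spatial intensity autocorrelation;
- **synthetic** — generators for every input (profiles, PIV-like fields,
  correlated images, rotated nuclei) with known ground truth.

## Worked example

Simulate a 40-frame recording of a 50 µm embryo with ground truth
ℓ = 16 µm, c = 0.58 and 0.3 µm/min velocity noise, then recover the
parameters:

```sh
chiralflow simulate --seed 1 --n-frames 40 --noise-sd 0.3 --out demo
chiralflow flowstats --piv demo/piv.csv --component x --out demo/vx.csv
chiralflow flowstats --piv demo/piv.csv --component y --out demo/vy.csv
chiralflow fit --intensity demo/intensity.csv \
    --vx demo/vx.csv --vy demo/vy.csv --out demo/fit.json
chiralflow vc --piv demo/piv.csv --out demo/vc.csv
chiralflow skew --nuclei demo/nuclei.csv --out demo/angles.csv
```

prints

```
ell = 16.031 ± 0.406 um, c = 0.582 ± 0.006
mean v_c = -0.674 um/min (40 frames)
wrote 1 skew angle rows to demo/angles.csv
```

The fitted hydrodynamic length and chirality index match the generating
values within their reported uncertainties; the negative mean `v_c` is the
handedness the model predicts for an anterior-high myosin gradient with
c > 0; and `angles.csv` reports the constructed 20° dorsal-view skew
(`ap_lr_deg = 20.0`, `dv_lr_deg = 0`).

The same analyses are available programmatically:

```python
from chiralflow import SyntheticSpec, make_velocity_profiles, fit_parameters

spec = SyntheticSpec(noise_sd=0.0)
I, frames = make_velocity_profiles(spec)
vx, vy = frames[0]
result = fit_parameters(I, vx, vy)
print(result.params.ell, result.params.c)   # 16.0, 0.58
```

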