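# stakit

Desk-scale **subtomogram averaging** (StA) for membrane channels with C4
symmetry: constrained alignment and missing-wedge-compensated averaging,
gold-standard half-set FSC resolution, multireference classification,
eigenvolume PCA of conformational modes, and membrane-curvature estimation
— plus a phantom generator that plants a recoverable ground truth for
every stage.

## The problem

Cryo-electron tomography images macromolecules *in situ*: many copies of a
particle (here, a ~2 MDa four-fold channel such as the skeletal ryanodine
receptor standing in native sarcoplasmic-reticulum membranes) are picked
from tomograms as cubic subvolumes. Each subtomogram is an unknown rigid
transform of the common density, observed through the **missing wedge** —
the unsampled region of Fourier space left by a ±60° single-axis tilt
series — with dose-dependent amplitude decay and heavy noise:

&nbsp;&nbsp;`p_i = W · D · (R_i, s_i) ∘ ρ + ε_i`

`stakit` estimates the poses `(R_i, s_i)`, the density `ρ` (with C4
symmetry applied about the channel axis), its resolution by Fourier shell
correlation between independently refined half-sets, the particles'
conformational classes and collective motion modes, and the local
curvature `1/R` of the membrane the particles sit on.

Key ingredients, in the field's standard notation:

* **Constrained cross-correlation** — correlation normalised only over
  Fourier voxels inside the particle's wedge `W` and the band limit,
  removing missing-wedge bias from both scoring and classification.
* **Compensated averaging** — `Σ wᵢ D Fᵢ / (Σ wᵢ Wᵢ D² )` with
  Tikhonov-regularised division and particle weights `wᵢ = max(ccᵢ, 0)`
  (contribution proportional to correlation with the reference).
* **Branch rule** — >500 particles: independent half-set refinement, FSC
  resolution at 0.143 (0.5 available); ≤500: single reference, final map
  restricted to 36 Å.
* **Eigenvolume PCA** — voxel-wise PCA over aligned class averages; the
  trivial first component (global amplitude) is dropped, modes renumbered,
  mode *informativity* = var(mode m)/var(mode 1), per-mode half-maps by an
  equal-size eigencoefficient split.
* **Curvature fit** — resample the map in spherical coordinates about a
  centre on the symmetry axis at distance R from the membrane; the R that
  makes the membrane flattest (minimal angular variance of its radial
  centroid) is the osculating radius; curvature = 1/R.

## Worked example

Simulate 60 noisy missing-wedge particles (box 32, SNR 0.5), refine them,
and fit the membrane curvature of a clean average:

```python
import numpy as np
from stakit import (
    AlignmentConfig, EnsembleSpec, PhantomSpec, SubtomogramAlignment,
    MembraneCurvatureModel, simulate_ensemble, make_scene,
)
from stakit.curvature import CurvatureConfig

pspec = PhantomSpec.scaled(32, snr=0.5)               # 2x-binned test scale
espec = EnsembleSpec(n_particles=60, init_pose_error_deg=4.0, seed=11)
ens = simulate_ensemble(espec, pspec)

cfg = AlignmentConfig(cone_range=8, cone_step=4, inplane_range=8,
                      inplane_step=4, shift_limit_a=8, seed=5)
model = SubtomogramAlignment(ens.volumes, ens.working,
                             reference=ens.class_volumes[0],
                             wedge=ens.wedge,
                             tilt_scheme=pspec.tilt_scheme, config=cfg)
print(model.fit("halfset").summary())

scene = make_scene(PhantomSpec.scaled(96, membrane_radius_nm=50.0))
fit = MembraneCurvatureModel(scene, CurvatureConfig(stem_exclusion_nm=15.0)).fit()
print(fit.summary())
```

Output:

```
Subtomogram alignment results
==============================================
particles                60
refinement branch        halfset
iterations               1
C4 symmetry              True
band limit (Å)           None
mean / median cc         0.549 / 0.549
resolution (Å)           13.95  (FSC 0.143)
Membrane curvature fit
==============================================
optimal radius (nm)      51.3
curvature (1/nm)         0.0195
membrane apex z (Å)      187.4
flat-sheet score         4.095 voxel²
centre side              lumenal
```

The 60 noisy particles refine to a 14.0 Å half-set resolution (Nyquist is
10.8 Å at this binning), and the flatness scan on the clean
receptor/membrane map recovers the planted 50 nm sphere radius to within ~3 % — `curvature`
is its reciprocal, ≈1/50 nm⁻¹.

The same stages run from the shell via the `sta` CLI
(`sta simulate | align | average | fsc | classify | modes | curvature |
run`), and `sta run config.yaml` executes the whole pipeline from one
YAML file with provenance stamping.

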