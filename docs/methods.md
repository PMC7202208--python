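# Methods

`stakit` implements a desk-scale subtomogram-averaging (StA) analysis for a
membrane channel with C4 point-group symmetry — the use case is the skeletal
ryanodine receptor (RyR1) sitting in native sarcoplasmic-reticulum (SR)
vesicle membranes — together with a synthetic-data generator that plants a
recoverable ground truth for every stage. This note records the model
behind each stage, the defaults and why they were chosen, the numerical
choices, and what the phantom tests do and do not demonstrate about real
data.

## Observation model

Each subtomogram is modelled as

&nbsp;&nbsp;`p_i = W · D · (R_i, s_i) ∘ ρ + ε_i`

where `ρ` is the underlying density, `(R_i, s_i)` a rigid rotation/shift,
`D` a radial exposure-decay filter, `W` the missing-wedge mask of a
single-axis tilt series, and `ε_i` white Gaussian noise. The tomographic
projection/back-projection cycle is replaced by direct Fourier wedge
masking: for alignment and averaging purposes the two sampling models are
equivalent, and the simplification keeps the forward model exactly
invertible for testing.

**Wedge geometry.** Tilt axis `y`, beam `z`. A Fourier voxel with in-plane
direction `(k_x, k_z)` is sampled iff the folded angle
`-atan2(k_z, k_x) ∈ [tilt_min, tilt_max]`; a hard ±60° wedge therefore
retains 2/3 of Fourier space (span/180). Voxels exactly on a wedge
boundary plane (the ±45° grid diagonals are fully populated with them)
carry weight 1/2 — with full weight the discrete count misses the analytic
fraction by >1.5 % at box 64 — and the retained fraction is measured inside
the Nyquist sphere, since the FFT-cube corners lie beyond Nyquist. The
default mask edge is a 1-voxel Gaussian.

**Exposure decay.** Radiation damage uses the standard critical-exposure
parameterisation `N_e(f) = 0.245 f^(−1.665) + 2.81` (f in 1/Å, N_e in
e⁻/Å²); each tilt is attenuated by `exp(−D_cum / 2 N_e)` at its cumulative
dose and the per-tilt factors are averaged into one radial amplitude
profile per particle. The dose-symmetric order `0, +3°, −3°, +6°, −6°, …`
gives the untilted image the lowest prior dose. Defaults follow the
acquisition being emulated: −60..+60° in 3° steps (41 tilts), 1.1 e⁻/Å²
per tilt, an 18 e⁻/Å² zero-tilt exposure, ≈62–68 e⁻/Å² total, 2.7 Å pixels
at full scale.

## Volume conventions

* Axis order `(x, y, z)`, 0-based voxel indices, positions in Å.
* Orientations are intrinsic Z–X–Z Euler triplets `(tdrot, tilt, narot)` in
  degrees, the parameterisation of StA particle tables. The matrix
  composes as `Rz(tdrot)·Rx(tilt)·Rz(narot)`; consequently the C4 symmetry
  quotient acts on `narot` (the template-frame spin), and the canonical
  pose folds `narot` into [0°, 90°) — at `tilt ≈ 0` the two z-angles merge
  and their sum is folded instead.
* Rotation centre is voxel `N/2` (0-based) for the even boxes used
  throughout; resampling is trilinear (adequate at the 20–40 Å resolutions
  targeted here, and cheap).
* Out-of-grid samples are filled with the *boundary-shell mean* (the local
  background level) rather than the global mean: for normalized real
  particles the two coincide, while for compact positive phantoms a
  global-mean fill would add spurious mass on every rotation (measured
  ≈15–20 % for generic poses) and thereby break mass conservation.
* C4 symmetrisation uses periodic boundary handling, under which a 90°
  rotation about voxel `N/2` is an exact grid permutation; a symmetric
  phantom is reproduced to float round-off.

## Constrained alignment

Scores are normalised cross-correlations computed only over Fourier voxels
inside both the particle's wedge and the band limit (DC excluded), which
removes the missing-wedge bias: a wedge-filtered copy of a map scores ≈1
against the unfiltered map. Translation search is a single FFT
cross-correlation restricted to a ± shift-limit window; rotation search is
a deterministic hierarchical grid — azimuth rings covering a cone of
directions at `cone_step`, crossed with in-plane spins at `inplane_step`
(quotiented to 90° under C4), followed by a half-step 3×3×3 local
refinement. When every particle starts from the identity pose the rotated
reference bank is computed once and shared across particles. The original
study's search ranges and iteration counts are not on record; the defaults
here (16° cone at 8°, 8° in-plane, one iteration plus local refinement)
are configuration, not claims about that run.

## Weighted averaging

Particles are moved back to the reference frame; the average divides the
weighted Fourier sum by the accumulated per-voxel sampling weight
(particle weight × its wedge rotated into the reference frame × D²), with
the data weighted by D (a matched filter): the signal is restored where it
was measured while noise at strongly damped frequencies is suppressed, not
amplified. Particle weight is `max(cc, 0)` — contribution proportional to
the correlation against the reference, negative scorers excluded.

The division is Tikhonov-regularised, `num·den/(den² + ε²)` with
`ε = 0.1·max(den)`. A small *floor* under the denominator was tried first
and rejected: dividing never-sampled voxels by a floor of `10⁻³·max`
amplifies interpolation leakage up to 1000-fold and drives the average's
correlation with the planted truth *below* that of a single raw particle
(0.19 vs 0.72 at n=100, SNR 0.5). With the regularised inverse the same
experiment gives 0.94, restoring the expected behaviour (average better
than any single particle, monotone in n). The regularisation acts as a
radial/anisotropic filter only where sampling is weak; FSC-based
resolution estimates are unaffected because FSC is invariant under
per-voxel filters applied to both half-maps.

## Half-set branch rule

Datasets with more than 500 particles are split at random (seeded, no
stratification; assignments persist in the particle table and are never
swapped) and the halves refined fully independently; resolution is read
from their FSC at the configured threshold, linearly interpolated between
1-voxel shells. Smaller sets are refined against a single reference and
the final map is restricted to 36 Å — the restriction uses a roll-off that
*ends* at the cutoff so that the product carries (numerically) no power
beyond it — and the reported "resolution" is that band limit. The
threshold for the FSC criterion defaults to 0.143 for independent
half-sets, with 0.5 available; the source protocol does not state which it
used, so neither value is asserted as "the" original one.

## Multireference classification

Poses stay fixed; K references are seeded by smooth random phase jitter
(σ = 0.25 rad, seeded) of the global average, and the loop alternates
assignment-by-best-constrained-cc (at the 22 Å classification band, C4
applied) with per-class compensated averaging. Monotonicity of the
objective (sum of best-class correlations) is enforced: an update that
would decrease it reverts and stops. A class that empties is reseeded once
from the worst-scoring tenth of the largest class, then allowed to die.
Convergence: <1 % label changes or 10 iterations. Because the local optima
of the alternation depend on the seeding, the whole loop is restarted from
five independent seedings (derived deterministically from the seed) and
the run with the best final objective is kept. Pruning removes classes
strictly below `min_fraction` (default 1 %) or manually flagged (the
artifact analogue of gold-bead classes); occupancies always sum to 1 over
retained + excluded.

## Eigenvolume analysis

Class averages (fully sampled — no wedge bookkeeping is needed at this
stage) are aligned to their evolving mean with a small full-band C4 local
search (≤5 rounds), then decomposed by voxel-wise PCA computed on the
class-count-sized Gram matrix (36 ≪ voxel count). The first raw principal
component of such sets tracks global amplitude/normalisation rather than a
motion; it is dropped unconditionally and modes are renumbered from the
second raw component, with a diagnostic reporting the dropped component's
correlation with the per-class voxel sum so the triviality can be
verified. Informativity is `var(mode m)/var(mode 1)`. Per-mode half-maps
average the lower- and upper-coefficient halves of the class set (odd
counts exclude the median volume so the groups stay equal-sized; class
averages are unweighted by particle count — an occupancy-weighted option
exists but is off, since the original procedure's weighting is unstated).
Spatial clustering of eigencoefficients is tested with Moran's I on a
symmetrised 6-nearest-neighbour graph with a seeded permutation null and a
one-sided (clustering) p-value.

## Membrane curvature

A map whose membrane lies on a sphere of radius R becomes a
constant-radius sheet in spherical coordinates about the sphere's centre.
The centre is constrained to the C4 axis (the average is symmetric, so the
osculating sphere's centre lies on it). The flatness functional — the
original work names the goal but not the functional — is the variance
across angular columns of the per-column membrane radial centroid
(voxels²), with the receptor-stem footprint excluded (default 10 nm; the
phantom tests at 1.5×-scaled geometry use 15 nm so the scaled lumenal
extensions stay inside the mask).

Membrane detection takes the *lowest* strong density band of each column,
not the global maximum: the receptor's cytoplasmic domain overhangs the
membrane at ≲20 nm off-axis and otherwise captures the centroid. The apex
height is pinned before the radius scan by an algebraic circle fit to the
membrane surface z(ρ) extracted from per-column centroids — scanning
radius and apex height jointly has a shallow diagonal valley that admits
spurious small-R optima. The radius is then scanned (default 20–200 nm in
10 nm steps plus a flat-sheet sentinel scored with the same functional
along z), polished by golden-section to 1 nm, with a small local apex
refinement. Maps are pre-smoothed by a 1-voxel Gaussian for band
detection. Curvature is `1/R`; the flat sentinel reports 0. For
receptor-free membrane patches both centre placements are fitted and the
better side gives the sign: positive = centre of curvature on the
cytoplasmic (+z) side (cytoplasm-concave); `|R| > 150 nm` counts as
near-flat. On noise-free phantoms the fit recovers planted radii of
35–100 nm within ~3 % and stays within 10 % at SNR 1.

## Synthetic generator: what it emulates, and what it does not

The phantom is a C4 "mushroom": a square cytoplasmic slab (240 Å wide,
110 Å tall at full scale), a transmembrane stem (35 Å radius), and four
40 Å lumenal extension rods, standing on a 40 Å-thick spherical membrane
patch (default R = 50 nm) whose sphere centre sits on the lumenal side.
Classes are parametric deformations of this geometry: lateral slab scaling
(peripheral-domain motion), vertical stretch, and membrane-radius
substitution. Poses are uniform in-plane with a near-membrane-normal tilt
(half-normal, σ = 8°, truncated at 15° — the real membrane-constrained
orientation distribution is only qualitatively known, so the spread is a
parameter, not a fixed fact). Rendering follows the observation model
above, with SNR defined as signal power over noise power *after* wedge and
dose filtering.

Study-condition defaults used by the recovery tests: box 64 at 5.4 Å
(2×-binned; 200³ at 2.7 Å is the full-scale geometry), n ≤ 660, SNR 0.5
for the population analyses and SNR 10 for pose recovery; 4-class
occupancies 45/27/19/10 of 101 (the reference percentages are rounded and
sum to 101, so the planted probabilities are those counts normalised).
Class deformation amplitudes (slab ×0.85; height ×1.25; and for the
least-populated class a 30 nm membrane with a mild ×1.12/×1.08
vertical/lateral extension, mirroring the description of that state as a
curvature change accompanied by cytoplasmic domain extension) were set
once so that class-conditional maps differ visibly at the 22 Å
classification band under SNR 0.5; they are coarser than the subtle domain
motions of the real receptor. A curvature-only class is *not* separable at
this scale — the sagitta difference across a 17 nm chord is sub-voxel.

What passing tests show: the estimators are consistent and unbiased on
data drawn exactly from the forward model, at planted effect sizes, and
the bookkeeping (branch rules, splits, quotients, tables) is correct. What
they do not show: robustness to CTF effects, colored noise, gold-fiducial
artifacts, neighbouring particles in crowded membranes, or deformations
outside the parametric family — none of which the generator produces (CTF
simulation is deliberately out of scope; noise is white by design, a
colored-noise option being deferred).

## Numerical details and degenerate inputs

* FFTs via `scipy.fft`, real-to-complex where possible; alignment caches
  rotated-reference spectra as complex64.
* FSC shells are 1 Fourier voxel wide; an all-zero shell reports 0; a
  curve that never crosses the threshold reports the Nyquist resolution; a
  curve starting below it warns and reports "worse than the first shell".
* Band-pass edges are 2-voxel raised cosines; total power can only
  decrease (Parseval-checked property test).
* Empty wedge/band overlap, zero total particle weight, all-identical PCA
  inputs, undetectable membranes, and occupancies not summing to 1 are all
  explicit errors or flagged degenerate results rather than silent NaNs.
* All randomness flows from per-stage seeds; the pipeline driver derives
  named substreams from one global seed, and a rerun with the same config
  and seed reproduces the particle tables bit-for-bit.

## Known limitations

* Translation peaks are voxel-resolution (no subvoxel interpolation); at
  5.4 Å voxels this bounds shift accuracy at ~2.7 Å.
* The shared rotated-reference bank applies only to global searches from
  identity poses; per-particle local searches re-rotate the reference.
* The classification objective is only guaranteed non-decreasing because
  decreasing updates are rejected; with very similar classes this can stop
  the loop early rather than escape a local optimum.
* Eigenvolume PCA mixes components whose variances are within sampling
  error of each other at K = 36 class averages; the informativity spectrum
  is more stable than the eigenvolumes themselves.
* The curvature model assumes a single osculating sphere centred on the
  symmetry axis; saddle-shaped or multi-scale membrane geometry is outside
  the model.
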