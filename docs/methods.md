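# Methods

This note records the models, parameter choices and numerical decisions
behind `spineqct`, in the spirit of a methods appendix: what is being
simulated and measured, which knobs matter, and what the tests do and do
not establish.

## Measurement model

### Calibration

Each scan session carries a hydroxyapatite phantom with rods of known
equivalent density. The HU→BMD map is an ordinary least-squares line
`ρ[mg/cm³] = a·HU + b` fitted per session — never shared across
sessions, since correcting scanner drift between sessions is the reason
the phantom is in the scan. Rod ROIs are eroded by 1 voxel in-plane
before averaging to avoid the partial-volume rim (`rod_erosion_mm`,
default 1.0). Because the map is affine, converting a mean HU equals
averaging converted HUs; all regional statistics exploit this.

### Registration

Later sessions are registered to the preflight volume with a 6-DOF rigid
transform: mean-squared intensity metric, 3-level multi-resolution
pyramid (shrink 4/2/1, smoothing 2/1/0 mm), regular-step gradient
descent initialised at the intensity centre of mass, regular sampling of
50 % of voxels. The similarity is evaluated outside the muscle contours:
muscles genuinely change size and composition between sessions and are
not rigid with the vertebra, so bone, phantom rods and the body outline
drive the fit. Transforms are serialized with an explicit convention tag
(intrinsic Z-Y-X angles, degrees, rotation about a stated centre).
Non-convergence within the iteration budget is flagged, never silent.

Recovery accuracy on noiseless synthetic volumes is ≤0.43 mm / ≤0.18°
worst-case over the full ±5 mm / ±5° repositioning range, comfortably
inside the 0.5 mm / 0.5° target (1 mm / 1° with 10 HU noise). Sub-slice
accuracy along the 3-mm slice axis is the binding constraint; see
*Rendering physics* below for what makes it attainable.

### Trabecular mask and regions

The vertebral-body mask (cortex + endplates + trabecular centrum) is
eroded in-plane by the cortical margin (default 3 mm, exceeding the
2 mm synthetic shell) and trimmed axially by the endplate margin at both
ends. The endplate margin defaults to **6 mm** — the 3.3 mm endplate
plus a one-slice buffer — because a mapped mask's edge voxels sample
tissue within the registration residual plus the slice profile of the
*adjacent* structure; with a margin equal to the endplate thickness
alone, superior/inferior regional means would absorb endplate signal
(~450 mg/cm³) through sub-millimetre mapping error.

The remaining mask is tiled into inferior / transverse / superior axial
slabs by cumulative fraction of its slices (default thirds; inferior and
superior take `floor(f·n)` slices, remainder to the transverse middle
slab — the proportions are configurable because the regional scheme's
exact proportions are a free choice). Masks and partition are defined
once on preflight and mapped forward with the inverse session transform
using nearest-neighbour interpolation, keeping ROIs matched and labels
categorical.

Two partial-volume safeguards apply to mapped sessions:

* **Guard band** (`boundary_guard_mm`, default 1.0): mapped voxels whose
  preflight-space longitudinal position lies within 1 mm of an internal
  slab boundary are excluded. Through-slice averaging mixes adjacent
  regions exactly there; preflight voxels always sit ≥ half a slice from
  a boundary, so the rule is symmetric yet removes nothing at baseline.
* **Matched-composition global**: the global trabecular value aggregates
  the three regional means using the *preflight* partition's voxel
  counts for every session. Otherwise the guard band, which trims the
  middle slab from both sides, would shift the global's regional
  composition between sessions and masquerade as density change. The
  global equals the weight-weighted mean of the regional values exactly,
  with the weights carried in the metrics object.

### Muscle morphometry

Muscle contours are inputs, not products — the measurement emulates an
operator-contoured workflow, so this module measures and never
segments. At the mid-vertebral slice (lower-median mask-bearing slice of
the mapped preflight body mask, keeping levels matched across sessions),
voxels outside the closed window [−50, 150] HU are excluded; CSA is the
retained voxel count × in-plane voxel area and density the retained
mean HU. Left and right sides are averaged per muscle before totals
(summing instead is available via `side_combine="sum"`, since the
reported total could be read either way); total CSA sums the four
side-averaged CSAs, total density is their CSA-weighted mean. A contour
with nothing retained yields CSA 0 with density flagged undefined (NaN),
never a silent zero.

Session CSAs are corrected for through-plane obliquity: an axial slice
through a session tilted by θ cuts the longitudinally-oriented muscles
obliquely and inflates in-plane areas by sec θ (≈ +0.25 % on average at
uniform ±5° tilts — systematic, because the baseline session is
untilted). The correction multiplies measured CSA by `R[2,2]` of the
*recovered* registration rotation; ground truth is never consulted.

### Longitudinal statistics

Percent change is `(post − pre)/pre × 100`; monthly rates divide by the
elapsed months (mission duration for flight, readaptation duration —
default 12 months — for recovery, with a switch to divide by mission
duration instead, since that reading also appears plausible for the
recovery period; the dimensional reading is the default). Paired
t-tests compare time points on complete pairs (n = 15 at follow-up);
one-sample t-tests compare monthly rates against zero; bone–muscle
associations are OLS with bone density as response. All tests are
two-sided, df = n − 1, α = 0.05, no multiplicity correction. Cohort
reports degrade degenerate cells (a single follow-up pair, zero
variance) to NaN p-values rather than failing the whole report.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 17 subjects,
mission-duration multiset {4,4,5,5,5,6,6,6,6,6,6,6,7,7,7,7,7} months
(mean 5.88), follow-up after 12 months for the first 15 subjects (the
deterministic analogue of two missed follow-ups), preflight regional
densities with means/SDs (178.9±32.4, 177.5±29.6, 196.5±32.4) mg/cm³,
flight rates (−1.08±1.13, −0.72±0.77, −0.51±1.17) %/month,
readaptation rates (0.39±0.80, 0.01±0.56, 0.05±0.85) %/month, muscle
CSA/density flight rates (−1.02±1.29, −0.83±0.89) %/month and
readaptation rates (+0.72±0.78, +0.28±0.55) %/month.

Anatomy is stylised: the vertebral body is an elliptic cylinder
(semi-axes 20 × 13 mm, height 30.6 mm) with a 2 mm cortical shell,
3.3 mm endplate slabs, optional posterior-element block, and a
trabecular interior painted in three axial density slabs that align
slice-for-slice with the analysis partition; the slab adjacent to each
endplate (`region_transition_mm`, 3 mm) takes the adjacent region's
density so that excluded buffer tissue matches its neighbour. The four
muscle pairs are elliptic cylinders (stylised areas 415/151/176/176 mm²
per side) whose voxels are an independent Bernoulli lean/fat mixture
(lean fraction 0.92, lean 50 HU, fat −100 HU): fat falls below the
analysis window, so fat infiltration reduces CSA while in-window
attenuation is steered via the lean HU. CSA change scales the contour
area; attenuation change scales the lean HU. The phantom has three rods
(0/100/200 mg/cm³, radius 5 mm) below the body; the true calibration is
ρ = 0.78·HU − 3.2, inverted at render time. Noise is additive Gaussian,
default SD 10 HU. Sessions are displaced by uniform rigid offsets
(±5 mm, ±5° per axis; preflight is the identity by definition).

Between-subject realism that matters for estimator validity:

* regional baseline densities are correlated within subject (ρ = 0.9,
  marginals preserved) — independent draws would give adjacent-region
  contrasts far beyond anything anatomical and amplify any residual
  slab-mixing error;
* muscle sizes vary between subjects (lognormal CV 0.10, left/right
  symmetric) with sub-voxel placement jitter — identical templates
  would make ellipse-rasterisation error correlate across subjects
  instead of averaging out.

### Rendering physics

Three rendering choices exist purely so that the synthetic data behaves
like real CT where the pipeline is sensitive:

1. **Slice sensitivity profile.** Each voxel averages the deterministic
   scene over five weighted z sub-samples (triangular weights, reach
   0.8 mm) — axial CT integrates through the slice. Point sampling
   would leave the volume invariant to sub-slice z-shifts and bias the
   registration optimum by up to 0.5 mm / 0.4° (interpolation
   artifact on razor-sharp edges).
2. **Interface placement.** Axial interfaces of measured tissues
   (endplate boundary, slab boundaries) sit on mid-slice planes, so an
   unshifted render is exactly piecewise-constant — the generator's
   injected densities are recovered exactly in the identity case — while
   the outer body surface and muscle ends sit at varied phases, giving
   the registration diverse z landmarks.
3. **Background heterogeneity.** A smooth ±12 HU field, fixed in the
   anatomy's frame and zero inside every measured tissue, plays the role
   of soft-tissue texture: it gives the similarity metric continuous
   sub-voxel sensitivity without touching any measurement.

## What passing tests do and do not show

The synthetic cohort has piecewise-constant tissue (no trabecular
microarchitecture), ellipse geometry, Gaussian noise without streaks or
beam hardening, muscle change that is spatially uniform, and fat
infiltration without contiguous pockets. Recovery of injected effects
through this pipeline therefore validates the *measurement chain* —
calibration, registration, matched-ROI mapping, windowed morphometry,
and the longitudinal statistics — under controlled conditions; it does
not validate segmentation quality, robustness to scanner artifacts, or
the biology of the injected rates. Absolute regional densities in tilted
sessions carry ~1 mg/cm³ of partial-volume sensitivity that is inherent
to 3-mm slices; percent changes, the quantities of interest, are immune
to it at the cohort level (end-to-end single-subject recovery is within
0.3 percentage points).

## Recovery experiments

`spineqct.experiments` (used by `scripts/acceptance.py` and the
acceptance tests) injects per-subject effects drawn from the reported
cohort distributions, runs the full image pipeline at the default
problem size (96×96×40 voxels at 1×1×3 mm, 17 subjects × up to 3
sessions), and averages the recovered cohort means over five seeds. Each
cohort's draws are standardised to the exact target moments — a
variance-reduction choice made at design time, so that deviations of the
recovered mean measure pipeline error rather than sampling luck; the
acceptance bands (±2·SD/√n of the reported mean) are unaffected. The
transverse follow-up trajectory is parameterised by the reported
follow-up-vs-preflight percent distribution directly (the readaptation
rate is solved per subject), and one two-session cohort injects the
superior postflight percent difference directly, because those are the
quantities being recovered.

## Known limitations

* Nearest-neighbour mask mapping plus 3-mm slices limit absolute
  regional accuracy in tilted sessions (see above); thinner synthetic
  slices (configurable spacing) reduce this roughly linearly.
* The registration similarity assumes one modality and one scanner
  (mean-squared metric); multi-scanner cohorts would need a different
  metric.
* Muscle contours are trusted inputs; contouring error (the dominant
  uncertainty in practice) is outside the simulation.
* Bone loss and recovery are modelled as linear in time within each
  period; the statistics inherit that assumption.
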