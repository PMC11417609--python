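# Methods

This note documents the models, numerical choices and known limitations of
`xcal`, stage by stage. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Synthetic phantoms and ground truth

Four analytic structures stand in for scanned bone: a parallel-plate
lattice (trabecular plates, thickness `t`, pitch `s`, normal to axis 0), a
square lattice of rods, a thresholded Gaussian random field (marrow-like
disordered structure), and a cortical plate perforated by through-thickness
cylindrical pores on a jittered lattice that guarantees non-overlap. Their
morphometric truth is known by construction, not measured from the raster:
plate BV/TV is exactly `t/s`, rod thickness is the rod diameter, shell
porosity is the summed analytic pore area over the shell area, and so on.
Because the truth derives from the declarative phantom description,
rasterising the same description at two grid sizes yields identical truth
fields, which makes the phantoms usable
as oracles for the measurement chain. Rasterisation places a voxel in the
phase when its centre falls inside the analytic solid; a grid is rejected
when the smallest structural feature spans fewer than two voxels
("unresolvable feature").

The pore count for a target porosity is rounded to an integer, so the
constructed porosity can differ from the requested value by up to half a
pore's area fraction; the analytic truth always reports the constructed
value.

## Scan simulation

A scanner profile is (voxel size, PSF width, noise SD, linear density
calibration). Imaging is: binary truth × tissue mineral density (default
1200 mgHA/cm³, the conventional fully-mineralised-matrix value), Gaussian
PSF blur, exact box-average resampling onto the scanner grid, additive
Gaussian noise. Two presets emulate the two device generations — 82 µm and
61 µm isotropic — with PSF σ = 0.6 × voxel size, so blur scales with
resolution. Neither device's true PSF or noise spectrum is public; the
profiles are deliberately qualitative, resolution-dominated stand-ins, and
no beam hardening, ring or motion artifacts are modelled. Conclusions drawn
from them are about the *direction* of resolution effects, not about
device-accurate magnitudes.

Numerical choices: the blur uses periodic boundary handling (the phantoms
are periodic when their extent is a multiple of the structural pitch), and
the resampler emits only output voxels whose physical box is fully covered
by the input, each as the exact average over its box. Gray means are
therefore unbiased, and total mineral mass (gray × voxel volume) is
conserved exactly when the extent is commensurate with the coarse grid —
otherwise a sub-voxel sliver at the far boundary is cropped. Downstream
masks trim one coarse voxel at volume borders so edge voxels never enter
statistics.

## Segmentation

**Gaussian + fixed BMD thresholds** (second-generation standard): Gaussian
filter (σ = 0.8 voxels, truncated at a 1-voxel support, matching
conventional practice) followed by fixed thresholds of 320 mgHA/cm³
(trabecular) and 450 mgHA/cm³ (cortical). Because the threshold sits at
~27% of matrix density, blur systematically *widens* above-threshold
structures and *fills* sub-voxel pores — the mechanism by which this
protocol overestimates BV/TV and Tb.Th and underestimates Ct.Po on fine
structure. All parameters are configurable.

**Laplace–Hamming + fixed global threshold** (first-generation protocol):
a frequency-domain filter `[(1−w) + w·(|f|/f_Nyq)²] · Hamming(|f|; c)` with
blend weight `w = 0.5` between the original image and its Laplacian
magnitude response, and a Hamming low-pass window cut off at `c = 0.4` of
Nyquist. The exact constants of the device implementation are not public;
these defaults are exposed in config and chosen to realise the documented
qualitative behaviour (edge/fine-feature enhancement with noise control).
Three further design choices matter:

- the DC bin of the response is zeroed, so the filtered image is zero-mean
  *contrast*. A single global threshold on the raw filtered image is
  meaningless when a large DC pedestal (proportional to mean compartment
  density) shifts the whole histogram; thresholding contrast is what makes
  "fixed global threshold" well defined across compartments. The Laplacian
  term destroys density calibration either way, so the threshold is
  specified as a fraction (default 0.4) of the maximum positive in-mask
  response rather than in mgHA.
- volumes are mirror-padded to the next even size before the FFT and
  cropped after, so the operator is exactly periodic only on even-sized
  inputs; the translation-equivariance tests use that path (`pad=False`).
- a constant input has zero contrast and yields an empty segmentation with
  a logged warning rather than an error.

A band-pass contrast filter cannot represent the interior of very thick
uniform regions perfectly: Gibbs-type undershoot next to strong edges can
dip below the global threshold and carve thin sheet artifacts inside a
thick cortex. The validation design accounts for this (see below); for
quantitative cortical porosity on thick cortices the Gaussian protocol or a
lower LH threshold fraction is preferable.

## Morphometry

**Local thickness** is the model-independent largest-inscribed-sphere
definition: the thickness at a voxel is the diameter of the largest sphere
containing it that fits inside the phase. On the grid, the sphere centred
at voxel `c` covers the voxels strictly closer than the Euclidean distance
transform value `dt(c)`, and its diameter is the axial voxel span
`2·(⌈dt⌉−1)+1`. This convention is exact for odd-width slabs and digital
balls and at most one voxel low for even-width slabs (no voxel centre lies
on the medial plane); the even-width bias is asserted explicitly in the
tests. The implementation discards sphere centres whose sphere is contained
in a 26-neighbour's sphere (a local redundancy check that provably never
changes the result) and propagates diameters from the surviving centres in
decreasing radius order; it is verified to agree *exactly* with an O(N²)
brute-force sphere-fitting oracle on all small fixtures, including random
structures. Comparisons on integer squared distances avoid floating-point
tie ambiguity.

**Trabecular outcomes**: Tb.Th and Tb.Sp are mean local thickness of the
bone and of the background-within-mask. Tb.N is the inverse mean spacing
between medial axes, where the axes are the ridge (non-redundant sphere
centres) of the bone distance transform and the spacing map is the local
thickness of the complement of the axes; Tb.1/N.SD is the SD of that map.
Tb.N requires at least two axis components (26-connectivity). The indirect
(first-generation-style) pathway derives BV/TV = Tb.BMD / matrix density,
Tb.Th = BV/TV / Tb.N and Tb.Sp = (1 − BV/TV) / Tb.N; on noise-free,
well-resolved phantoms with matching matrix density it agrees with the
direct pathway within 2%.

**Cortical outcomes**: Ct.Po is the pore fraction of the cortical mask,
Ct.Th the mean local thickness of the cortical bone, Ct.Po.Dm the mean
local thickness of the pore phase (reported missing, not zero, when no
pores exist). Ct.Pm uses marching-squares contour length per slice
(longest contour = periosteal boundary), averaged along the scan axis;
voxel-edge perimeter counting was rejected for its systematic
overestimation. Areas are mean per-slice mask areas; densities are mean
calibrated values over masks. Internal units: lengths mm, densities
mgHA/cm³.

## Cross-calibration

The calibration model regresses the second-generation value on the
first-generation value (that is the estimation direction actually needed:
XCTII\* from XCTI). The procedure follows the hybrid design exactly:
split 24 training / 12 test, 1000 bootstrap draws of 12 training pairs
with replacement, closed-form OLS per draw, averaged slope/intercept, and
reported R² = mean per-draw R². Draws of 12 from 24 are unconventional
(not full-size resamples) but are retained as the procedure under study;
`draw_size` is configurable. Degenerate draws (all x identical) are
redrawn rather than skipped, so exactly `n_boot` fits enter the average
with uniform weight; redraws are counted and logged. A perfectly constant
y within a draw is fitted exactly by a constant and assigned R² = 1.
Incomplete pairs are dropped pairwise per parameter and counted. Fixing
the seed fixes the split and all draws bit-exactly.

Verified properties: on a noise-free line the procedure returns the exact
coefficients with R² = 1 in every iteration; with draw size equal to the
training size the bootstrap-mean slope converges to the full-sample OLS
slope; across the slope range 0.23–1.77 at R² ≈ 0.9 the mean recovered
slope over 100 replicate cohorts is biased < 5%, with recovery error
monotone in noise.

## Validation statistics

Percent error is per-subject |XCTII\* − XCTII| / XCTII × 100; the summary
reports the mean with a t-based 95% CI (the parenthetical ranges in
published tables of this kind are interpreted as such CIs — an assumption,
flagged here). Subjects with measured value 0 are excluded with a warning.
Bland–Altman reports mean difference, limits of agreement mean ± 1.96 SD,
and proportional bias as the OLS slope of differences on means with its
two-sided p (flagged at p < .05; undefined and flagged when the means are
constant). The standard-vs-LH comparison is a paired two-sided t-test on
per-subject absolute percent errors (the test identity is not standard in
the field's reports; paired t is the natural choice for same-subject
re-analysis, and degenerate zero-variance differences return p = 1 or 0).
R² classification uses open intervals; boundary values fall to the lower
class with a warning. Monte-Carlo checks: LoA cover 95% ± 2% of Gaussian
differences at n = 10⁴, and the paired test's type-I error at α = .05 is
0.05 ± 0.01 over 2000 null replicates.

## Cohort simulator

The measurement-level simulator draws the first-generation value from a
normal population distribution per parameter and forms the
second-generation value as slope · x + intercept + noise, with noise on
the second-generation side only (matching the regression direction). The
default regimes span slopes 0.23–1.77 and R² 0.21–1.0 across the 14
outcomes at both sites and both analysis methods, with population means
and SDs set to plausible adult distal-site values on the first-generation
scale; the noise SD for a target R² follows from
R² = s²V / (s²V + n²). What the simulator does *not* model: non-linearity,
heteroscedasticity, motion-artifact outliers, and correlation between
parameters within a subject. Passing recovery tests therefore show the
estimator is correct under the linear-Gaussian model, not that real
inter-scanner relationships are linear.

## Validation design for the mechanism tests

Two phantom experiments reproduce the known direction of protocol
differences. (1) Resolution: a 150 µm thin-plate lattice (thinner than
three coarse voxels) measured through the Gaussian protocol gives
Tb.Th(82 µm) > Tb.Th(61 µm) > truth. (2) Fine pores: 70 µm pores (below
the coarse voxel size) in a 1 mm shell are measured via the
Laplace–Hamming arm as the porosity *difference* between the perforated
shell and an otherwise identical pore-free shell imaged and segmented the
same way. This paired design cancels the filter's thick-cortex sheet
artifact, which is common to both shells, and isolates the pore signal:
the difference is ≈ 0.04 at 61 µm and ≈ 0 at 82 µm. On thick features
(4 mm plates at 10 mm pitch) the two segmentation protocols agree within
2% of voxels, confirming that the method differences are confined to the
resolution limit.

## Pipeline and reproducibility

A single YAML config drives phantom generation, dual-profile imaging,
segmentation, morphometry, cohort simulation, calibration and validation.
All randomness flows from one master seed through spawned generators; the
two analysis methods share the cohort split so the method comparison is
paired. Outputs are CSV/JSON with fixed numeric formatting, and the run
manifest records the config hash, per-stage timings, warnings (excluded
subjects, redrawn draws, unresolved pores) and a SHA-256 checksum of every
artifact; identical configs produce byte-identical data files. The demo
config runs the full-size procedure (36 subjects, 1000 draws, three
phantom/profile arms) in well under a minute on one CPU; the problem sizes
in the tests (phantom extents of 2–20 mm at a 20–25 µm truth grid) were
chosen as the smallest geometries whose discretisation error is comfortably
inside the stated tolerances.

## Known limitations

- Scanner profiles are qualitative; absolute phantom outcomes should not
  be compared against device measurements.
- The Laplace–Hamming constants are package defaults, not the device's
  proprietary coefficients; only directionally robust conclusions are
  asserted.
- Even-width structures measure one voxel thin under the discrete
  largest-inscribed-sphere convention.
- No confidence intervals on calibration slopes (point equations only, as
  in the procedure under study); no multiple-testing correction.
- In vivo contouring is out of scope: compartment masks are analytic.
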