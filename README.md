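# xcal

Cross-calibration toolkit for dual-scanner HR-pQCT bone-microarchitecture
studies.

High-resolution peripheral quantitative computed tomography (HR-pQCT)
measures trabecular and cortical bone microarchitecture in vivo at the
distal radius and tibia. The transition from first-generation scanners
(XCTI, 82 µm isotropic voxels, Laplace–Hamming binarization, partly
indirect morphometry) to second-generation scanners (XCTII, 61 µm voxels,
Gaussian binarization, direct distance-transform morphometry) breaks the
comparability of longitudinal and multi-centre data: the same limb yields
systematically different BV/TV, Tb.Th, Ct.Po and related outcomes on the
two devices. `xcal` implements the full analysis chain needed to study and
correct this: synthetic dual-resolution acquisitions of analytic bone
phantoms, both binarization protocols, direct and indirect morphometry,
bootstrap linear-regression cross-calibration, and percent-error /
Bland–Altman validation. It is aimed at researchers who need a tested,
reproducible reference implementation of these methods — the imaging data
of such studies are rarely public, so every stage here is exercised against
simulated inputs with known ground truth.

## The model

For each outcome parameter `p`, cross-calibration assumes a linear
inter-scanner relationship

    XCTII_p = a_p · XCTI_p + b_p + ε

and estimates `(a_p, b_p)` by a hybrid of cross-validation and
bootstrapping: the paired cohort (n = 36) is split into 24 training and 12
test subjects; 1000 bootstrap draws of 12 pairs (with replacement) from the
training set are each fitted by ordinary least squares, and the averaged
slope, intercept and R² over the 1000 fits form the calibration equation.
Applying the equation to held-out XCTI values yields estimated
second-generation outcomes, written XCTII\*, which are validated against
the measured XCTII values via mean absolute percent error (with t-based 95%
CI), Bland–Altman limits of agreement, and a proportional-bias test.
Correlations are classified strong (R² > 0.9), moderate (0.7 < R² < 0.9) or
weak (R² < 0.7).

Upstream of the statistics, the package implements the image chain that
produces the outcomes: Gaussian-filter + fixed-BMD-threshold segmentation
(the second-generation standard), Laplace–Hamming filter + fixed global
threshold (the first-generation protocol, also applicable to
second-generation data), and model-independent morphometry by
largest-inscribed-sphere local thickness, medial-axis spacing (Tb.N,
Tb.1/N.SD), and compartment densitometry/geometry — 14 outcomes in total
(Tt.BMD, Tb.Ar, Tb.BMD, BV/TV, Tb.N, Tb.Th, Tb.Sp, Tb.1/N.SD, Ct.Ar,
Ct.BMD, Ct.Pm, Ct.Po, Ct.Th, Ct.Po.Dm).

## Worked example

Simulate a measurement-level paired tibia cohort at the package's default
inter-scanner regimes, calibrate every parameter, and validate one of them:

```python
from xcal import (CohortSimSpec, generate_paired_cohort, reference_regimes,
                  CalibrationStudy, percent_error)

spec = CohortSimSpec(n_subjects=36,
                     parameters=reference_regimes("tibia", "standard"),
                     seed=20260925)
xcti, xctii = generate_paired_cohort(spec)

study = CalibrationStudy(xcti, xctii)
equations, estimates = study.run(n_test=12, n_boot=1000, draw_size=12, seed=1)
print(equations.round(3).head(6))
print(study.equations["BV/TV"].summary())

test_xctii = xctii.subset(study.plan.test_ids)
err = percent_error(estimates["BV/TV"], test_xctii)
print(f"BV/TV mean absolute percent error: {err.mean:.2f}% "
      f"(95% CI {err.ci_low:.2f}-{err.ci_high:.2f}, n={err.n})")
```

Output:

```
           slope  intercept  r_squared  n_boot  n_train  redraws
parameter
BV/TV      1.685      0.005      0.989    1000       24        0
Ct.Ar      1.000      5.244      0.983    1000       24        0
Ct.BMD     0.904     72.197      0.965    1000       24        0
Ct.Pm      0.989      1.722      0.993    1000       24        0
Ct.Po      0.432      0.003      0.835    1000       24        0
Ct.Po.Dm   1.424     -0.034      0.556    1000       24        0

Cross-calibration equation: BV/TV
  XCTII* = 1.685 * XCTI +0.005235
  mean R^2 over 1000 bootstrap fits: 0.9890
  bootstrap slope SD 0.04708, intercept SD 0.008077
  training pairs 24, draw size 12, degenerate draws redrawn 0

BV/TV mean absolute percent error: 2.76% (95% CI 1.14-4.39, n=12)
```

The cohort was simulated with a true BV/TV slope of 1.66 and intercept
0.01 plus noise calibrated to R² = 0.99; the bootstrap recovers 1.685 ±
0.047 with mean R² 0.989, and applying the equation to the 12 held-out
subjects estimates their second-generation BV/TV to within ~3% on average.
`Ct.Po.Dm` illustrates the weak-correlation regime (R² ≈ 0.56), where
estimation errors are correspondingly larger.

The image chain can be run end to end from a single config:

```bash
xcal run --config examples/demo_config.yaml
```

which rasterises a thin-plate trabecular phantom and a perforated cortical
shell, images both at 82 µm and 61 µm, segments them with both protocols
(Laplace–Hamming on the first-generation arm; Gaussian and Laplace–Hamming
on the second-generation arm), measures the outcomes, and writes cohort
tables, calibration equations, validation statistics and a checksummed run
manifest to `demo_output/`. Reruns of the same config are byte-identical.
Subcommands `simulate`, `segment`, `measure`, `calibrate` and `validate`
expose the individual stages.

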