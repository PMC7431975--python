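# ihmt

Analysis toolkit for silent (zero echo-time) inhomogeneous
magnetization transfer (ihMT) brain imaging: ratio-map computation,
test-retest reliability, and head-orientation confound analysis.

## What it is for

ihMT is a myelin-specific MRI contrast built from the difference between
dual-offset (frequency-alternating) and single-offset RF saturation,
which is sensitive to the dipolar order of myelin lipids.  A silent
ihMT protocol acquires six weighted volumes per scan — an unsaturated
reference `S0`, single-sided `S+` and `S-`, dual-sided `S+/-` and
`S-/+`, and a T1-prepared volume `ST1` — using a RUFIS/ZTE readout
interleaved with saturation pulse trains.  This package is for anyone
who needs to turn those volumes into quantitative maps and study-level
statistics:

    MTR      = 1 - (S+ + S-) / (2 S0)
    eMTR     = 1 - (S+/- + S-/+) / (2 S0)
    MTasym   = (S+ - S-) / S0
    ihMTR    = 2 (eMTR - MTR)
    ihMTRinv = 2 ST1 (1/S+/- + 1/S-/+ - 1/S+ - 1/S-)

On top of the voxelwise maps it implements the repeatability and
confound analyses such a study needs:

* **ROI statistics** in native space (atlas labels pulled through a
  concatenated affine chain), between- and within-subject coefficients
  of variation, per-ROI group summaries;
* **ICC(2,1)** from a two-way random-effects model
  `y_ij = mu + s_i + r_j + e_ij`, with variance components estimated by
  REML regularised by a weakly informative gamma prior (shape 2,
  rate 0.5) on the random-effect SDs, percentile-bootstrap confidence
  intervals over subjects, and the poor/moderate/good/excellent
  classification at 0.5 / 0.75 / 0.9;
* **head-orientation analysis**: the angle between the scan's Z axis
  and the atlas Z axis extracted from affine transform chains, and a
  linear mixed model `value ~ angle + ROI + angle:ROI + subject` with
  subject-by-ROI and per-scan random intercepts, tested with
  Satterthwaite-type F-tests;
* **protocol timing arithmetic** for the silent sequence (segment and
  preparation times, dummy-scan preamble, total duration, RMS
  saturation amplitude);
* a **synthetic-study generator** (digital head phantom, known tissue
  ratios, subject/scan variance components, per-session head rotations
  with a linear angle effect, Rician noise) that makes the entire
  pipeline testable end to end without any acquired data.

`docs/methods.md` describes the models, defaults and limitations in
detail.

## Worked example

Simulate a 12-subject, two-session, two-repeat study at the default
(realistic) effect sizes, then run the reliability and orientation
analyses:

```python
from ihmt.simulate import PhantomSpec, simulate_roi_table
from ihmt.reliability import table_to_matrix, icc_report
from ihmt.orientation import fit_angle_model

spec = PhantomSpec(seed=42)
table, angles = simulate_roi_table(spec)

y = table_to_matrix(table, "genu_cc", "ihmtr_inv")
res = icc_report(y, n_boot=1000, seed=7)
print(f"genu ICC(2,1) = {res.icc:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}]")

m = fit_angle_model(table, angles, metric="ihmtr_inv")
print(f"angle slope = {m.slope_angle:.2e} per degree, "
      f"F = {m.f_angle:.1f}, p = {m.p_angle:.2e}")
print(f"interaction: F = {m.f_interaction:.2f}, p = {m.p_interaction:.2f}")
```

prints

```
genu ICC(2,1) = 0.381 [0.053, 0.594]
angle slope = -4.33e-04 per degree, F = 61.3, p = 2.95e-11
interaction: F = 1.19, p = 0.30
```

Reading this: the genu's ICC point estimate for this particular
simulated study is 0.38 with a wide bootstrap interval — single-study
ICCs at 12 subjects are noisy, which is exactly what the interval
shows.  The orientation model recovers the injected effect: inverse
ihMTR falls by about 4.3e-4 (0.043 percentage points) per degree of
head rotation, a highly significant main effect, while the
angle-by-ROI interaction is null — the effect is homogeneous across
ROIs, as generated.

The same steps are available from the shell:

```bash
ihmt timing                                   # protocol arithmetic table
ihmt simulate --seed 42 --out study/          # write a synthetic study
ihmt maps --s0 ... --st1 ... --out maps/      # ratio maps from six volumes
ihmt roi --maps maps/ --labels labels.nii.gz --out roi.csv
ihmt icc --roi roi.csv --metric ihmtr_inv --boot 1000 --seed 7 --out icc.csv
ihmt angle --transforms mt2t1.txt t12tpl.txt tpl2mni.txt
ihmt angle-model --roi roi.csv --angles angles.csv --out model.json
```

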