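# Methods

This note documents the models, estimators and numerical choices behind
`ihmt`, and what the synthetic validation does and does not demonstrate.

## Ratio maps

One ihMT scan comprises six co-registered volumes: the unsaturated
reference `S0`, single-sided saturated `S+` and `S-` (positive /
negative offset frequency), dual-sided frequency-alternating `S+/-` and
`S-/+`, and a T1-prepared volume `ST1`.  The five derived ratios are

    MTR      = 1 - (S+ + S-) / (2 S0)
    eMTR     = 1 - (S+/- + S-/+) / (2 S0)
    MTasym   = (S+ - S-) / S0
    ihMTR    = 2 (eMTR - MTR)
    ihMTRinv = 2 ST1 (1/S+/- + 1/S-/+ - 1/S+ - 1/S-)

All are dimensionless fractions, invariant under a common rescaling of
the six signals (receive-gain independence), which the tests assert to
1e-8 relative.  The inverse ihMT ratio scales reciprocal signals by the
T1-prepared image, which damps T1- and B1-related modulation of the
plain ihMTR.

Numerical choices: any voxel whose denominator is non-positive becomes
NaN rather than being clipped, so downstream statistics can drop it
explicitly; NaN is the universal mask value.  Background is excluded by
`S0 > 0.05 * max(S0)` by default — the choice of background cut is not
critical for ROI statistics because ROI labels live well inside the
head — and an explicit mask file overrides the threshold.  For
`ihMTRinv` the four saturated signals must also individually exceed the
threshold, since their reciprocals diverge for dead voxels.  Negative
ratio values are never clipped before ROI averaging.

## Protocol arithmetic

`ProtocolTiming` holds the primitive sequence parameters of the silent
ZTE/RUFIS ihMT protocol (TR 1.764 ms, 32 spokes per segment, a train of
10 Fermi pulses of 500 us width and 500 us gap at 8.75 uT RMS, 48 dummy
segments, 65 s per volume, five volumes).  The derived quantities are
pure arithmetic: segment time = spokes x TR + ramp/switch overhead,
preparation time = train length + dead time, module RMS B1 = pulse RMS
x sqrt(duty cycle) over the nominal pulse-train window, dummy preamble
= dummies x segment time, and total time = volumes x (per-volume time +
preamble).  The two overheads are not primitive protocol numbers; they
are back-computed once so that the published segment and preparation
totals (68.6 ms and 10.8 ms) hold exactly, and dummy segments are
costed without an interleaved preparation train (48 x 68.6 ms = 3.3 s,
which is consistent with the published preamble duration, whereas
including preparation would not be).  Five volumes at 65 s plus the
preamble reproduce 5 min 41 s, so the per-volume scan time is treated
as excluding the preamble.

## Synthetic study generator

The generator exists so that every analysis stage can be validated
end-to-end without any acquired data.  It emulates:

* **Anatomy** — an ellipsoidal head with a GM shell, WM core and
  central CSF "ventricles" on a configurable grid (default 64^3 voxels
  of 3 mm); ten labelled boxes (labels 11-20) carved into WM stand in
  for bilateral tract ROIs of a WM atlas.  Default ROI box size is 5^3
  voxels at the default grid.
* **Tissue truths** — per-tissue `(S0, MTR, eMTR, MTasym, ST1/S0)`
  chosen once to echo in-vivo scales: WM ihMTR 0.12 and ihMTRinv 0.15,
  lower GM values, per-ROI dual-sided ratios laddered over the reported
  WM tract range, and a CSF compartment whose dual-sided ratio sits
  slightly *below* its single-sided one so the characteristic small
  negative ihMTR of fluid is exercised.  The T1-prepared signal
  fraction (0.37 in WM) is set so that the implied ihMTRinv matches its
  reported WM scale.
* **Design** — 12 subjects x 2 sessions x 2 repeats.  A subject effect
  `u_i ~ N(0, sd_subject^2)` and an independent per-scan effect
  `w ~ N(0, sd_scan^2)` shift the WM-family eMTR additively.  Defaults
  `sd_subject = 1.2e-3` and `sd_scan = 4e-4` (eMTR fraction units) were
  chosen so that, combined with the ROI-mean noise implied by the
  default SNR and ROI size, the generator's true ICC sits near 0.6 —
  the middle of the reported moderate-to-good reliability range.
* **Head orientation** — one angle per session,
  `theta ~ N(7, 5^2)` degrees truncated at zero (echoing the reported
  median 7 deg, quartiles 3.2-10.3 deg), shared by the session's two
  repeats.  The angle effect is a linear decrement of WM-family eMTR,
  `angle_slope = 1.2e-4` per degree, homogeneous across ROIs.  The
  slope was calibrated analytically — once, before any test was run —
  so that the implied within-subject t-statistic matches the magnitude
  of the reported orientation effect (F ~ 28 on ~ 24 sessions).  Each
  scan's native-to-atlas transform is emitted as the rotation by
  `-theta` about the x-axis, so the angle-extraction code recovers
  theta exactly; by default the image grid itself is not rotated
  (registration is out of scope, the transform *is* the ground truth).
* **Noise** — Rician: each voxel becomes `sqrt((x+n1)^2 + n2^2)` with
  `n1, n2 ~ N(0, sigma^2)`.  Default `sigma = 1` against WM `S0 = 100`
  (voxel SNR 100), where the Rician bias of the ratios is negligible;
  the tests verify the Rayleigh mean at zero signal.

Randomness is organised as one master seed with fixed per-scan
substreams, so outputs are bit-reproducible and adding subjects never
reshuffles existing scans.

Two simulation levels are provided.  `simulate_study`/`iter_study`
produce volumes, transforms and a truth table; replicate-study
statistics instead use `simulate_roi_table`, which draws each ROI's
mean signals directly with `N(0, sigma^2/V)` errors (V = ROI voxel
count) and passes them through the ratio definitions.  At SNR 100 this
Gaussian surrogate for the ROI mean of voxelwise Rician noise is
accurate to well below the effect sizes studied, and it makes 300-study
power simulations tractable.

What passing these tests does *not* show about real data: the phantom
has no anatomy-driven partial voluming, no B0/B1 inhomogeneity, no
motion or registration error, no tract-orientation dependence within
ROIs, and the angle effect is injected on eMTR by construction (the
acquisition cannot distinguish which saturated signal carries it).

## ROI statistics and CoV

ROI means are arithmetic means of non-NaN voxels per label, computed in
native space after pulling the atlas labels through the concatenated
affine chain with nearest-neighbour sampling (labels are categorical;
resampling once minimises interpolation).  Between-subject CoV is the
sample SD (n-1) over the mean across all scans and subjects;
within-subject CoV is each subject's CoV over their four scans,
averaged unweighted over subjects.  Group summaries report, per ROI,
the mean over all scans and the SD of the four scan-occasion group
means; the published table's SD column is compatible with this reading
(its values are far smaller than the between-subject spread), but the
original definition is not stated, so this is a documented choice.

## Reliability: penalised ICC(2,1)

Measurement model: `y_ij = mu + s_i + r_j + e_ij` with subjects `i`
crossed with scan occasions `j` (session and repeat flattened to four
levels), all effects independent Gaussians, and

    ICC(2,1) = var_s / (var_s + var_r + var_e).

Variance components are estimated by REML with a gamma(shape 2, rate
0.5) prior on the subject and scan standard deviations (residual
unpenalised).  The prior is zero-avoiding (shape > 1), which removes
the boundary estimates that plague small-sample REML — the tests show
strictly fewer zero-variance estimates than unpenalised REML — at the
price of a small downward ICC bias (~0.03 at ICC 0.7 with 12
subjects).  The prior is applied on the scale of the data standardised
by its overall SD, making the estimator exactly invariant under affine
rescaling of the measurements; an absolute-scale prior cannot be
scale-invariant, and the invariance was judged the more important
property for a ratio statistic.  One consequence worth knowing: the
scan factor has only `k-1 = 3` degrees of freedom however many subjects
are scanned, so the prior's imprint on `var_scan` does not vanish
asymptotically (~25% at 200 subjects in the tests), while `var_subject`
and `var_resid` converge to the ANOVA estimates.

Balanced tables use an exact closed-form REML criterion built from the
three ANOVA sums of squares (each fit ~1 ms, which makes the bootstrap
and the replicate studies cheap); tables with up to 20% missing cells
fall back to a dense generic REML.  Optimisation is over log-SDs with
analytic gradients, deterministic ANOVA starting values, convergence
tolerance 1e-8, and bounds that keep the covariance matrix comfortably
invertible.  The unpenalised core reproduces lme4's REML components to
six decimals on a reference dataset.

Confidence intervals: percentile bootstrap resampling subjects with
replacement (each kept subject retains its full four-scan record),
2.5/97.5 percentiles of the refitted ICCs, seeded.  **Known
limitation:** at 12 subjects this interval undercovers — measured 84-85%
instead of the nominal 95% at true ICC 0.7, regardless of the prior and
of the number of resamples.  The subject-level percentile bootstrap
cannot recentre a downward-biased ratio estimator, and this should be
kept in mind when reading such intervals; the corresponding validation
test records the shortfall rather than hiding it.

Categories: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent,
boundaries assigned upward.

## Head orientation

The per-session angle is extracted from the concatenated affine chain
(native -> T1 -> template -> atlas) by applying its linear part to
Z = (0, 0, 1) and taking the angle to Z via the numerically stable
`atan2(|v x Z|, v . Z)` form; the vector is normalised (the chain may
scale) and translation is ignored.  The angle is unsigned, exact to
1e-9 degrees for pure rotations, and shared by a session's repeats.

The angle model for one metric is the linear mixed model

    value ~ angle + ROI + angle:ROI + subject      (fixed)
            + (1 | subject:ROI) + (1 | scan)       (random)

with sum-coded ROIs, so the `angle` coefficient is the ROI-averaged
within-subject slope.  Two deliberate departures from the obvious
transcription of "a random and fixed effect for each participant":
a pure subject random intercept is omitted because it is exactly
aliased with the subject fixed effects (its likelihood is flat), and a
per-scan random intercept is included because the ten ROI values from
one acquired volume set share that scan's realisation — without it the
model treats them as ten independent observations of a session-level
covariate and the angle test becomes strongly anticonservative (~30%
type-I error in a pilot calculation, versus 3.5% with the term over the
canonical 200 null studies; the accepted band is 2-10%).

Significance uses Wald F-tests with Satterthwaite denominator degrees
of freedom (delta-method variance of each contrast eigencomponent
against the numerical information matrix of the variance parameters,
pooled as in the standard mixed-model ANOVA implementations), applied
to the Kenward-Roger small-sample-adjusted covariance of the fixed
effects; in this near-balanced design the KR inflation is analytically
negligible, so the Satterthwaite df carry the correction.  The df were
validated against the exact value (18) in a balanced one-way design.
Rank-deficient designs (for example a single session per subject, which
aliases angle with the subject effects) are rejected with a message
naming the aliased term.

## Validation suite sizes

The acceptance-style tests run, per invocation: a 64^3 noise-free
round trip (exact to 1e-10); ICC recovery at four reliability levels
(50 replicate 12 x 4 studies each, mean within 0.1); bootstrap coverage
at ICC 0.7 (200 studies x 200 resamples); angle-model size and power
(200 null + 100 alternative replicate studies at the default effect);
and 50 replicate studies for the CoV ordering.  These sizes keep the
whole suite in the ten-minute range on one CPU while leaving the
Monte-Carlo error of each check well inside its asserted band.
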