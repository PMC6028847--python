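# Methods

This note documents the models behind `dwiqc`, their assumptions, the default
parameter values and why they were chosen, and what the synthetic phantoms do
and do not establish.

## Signal model and ADC fitting

Diffusion-weighted signal is mono-exponential per compartment:

    S(b) = S0 · exp(−b · ADC)

with b in s/mm² and ADC in mm²/s. The two-point map is the closed-form
inverse, `ADC = ln(S(b_low)/S(b_high)) / (b_high − b_low)`; the multi-b map is
minus the ordinary-least-squares slope of ln S on b, which reduces bit-for-bit
to the two-point form for two b-values. No intra-voxel incoherent motion
(perfusion), kurtosis, or T2 effects are modelled: the phantoms are water and
homogeneous solids, where mono-exponential decay is accurate.

Voxels whose signal does not exceed a configurable floor (default 0, i.e. all
strictly positive signals are used) are *masked invalid*, never zero-filled —
zeros would corrupt ROI means and SDs. Real console software applies such
thresholds with undocumented values, which is why the floor is exposed rather
than fixed.

## Phantom synthesis

**Geometry.** Scenes are unions of non-overlapping spheres and z-axis
cylinders in continuous mm coordinates with the scanner isocentre at (0,0,0);
voxel centres sit at `origin + (index + 0.5)·spacing`. Partial-volume
fractions per voxel are computed by sub-voxel sampling (default 5 per axis,
i.e. 125 sub-centres per voxel).

**Signal-domain partial volume.** A mixed voxel's signal is the
fraction-weighted sum of per-compartment signals,
`S(b) = Σ_c f_c·S0_c·exp(−b·ADC_c)` — what the scanner's voxel integration
does. Mixing signals, not ADCs, is what creates the nonlinear small-sphere
errors: the log of a sum is not the sum of logs.

**Gradient-nonlinearity bias.** A separable per-axis polynomial (zero
intercept, distances in cm) multiplies the true ADC:
`ADC_meas = ADC_true · (1 + ε(x,y,z))`, so ε is exactly 0 at the isocentre.
The shipped default is a degree-2 least-squares fit to a measured vertical
profile on a 1.5 T system (0, −0.9, 9.3, 13.0, 24.1 % at 0–8 cm) with a flat
horizontal trend. Bias is evaluated at voxel centres before signal mixing.

**Noise.** Magnitude-MRI noise is Rician:
`out = sqrt((v + g1)² + g2²)`, g1, g2 ~ N(0, σ²) independent; σ = 0 is the
identity. A Gaussian option exists for analytic checks. Repeats share the
noiseless signal and differ only in their noise stream (spawned from one seed;
identical seeds give bit-identical series).

**Standard scenes.**

* *Ice-water phantom*: a 200-mm water cylinder (ADC 1.1 × 10⁻³ mm²/s, the 0 °C
  reference value; S0 = 1000) on a 79×79×11 grid at 4 mm (FOV ≈ 320 mm,
  protocol b = 0/100/600/800 s/mm², 4 repeats). The odd matrix places the
  isocentre on a voxel centre so centred ROIs and 20-mm shifts are exact.
  Thermal equilibrium is assumed; no temperature drift is modelled.
* *Sphere phantom*: six water spheres (10, 13, 17, 22, 28, 37 mm;
  ADC 2.0 × 10⁻³ mm²/s, room temperature) on a 55-mm ring, in a low-signal
  solid background (S0 = 10 % of water, ADC 0.3 × 10⁻³ mm²/s) so that VOI
  contamination is visible; clinical grid 2.5 mm in-plane, 5-mm slices,
  b = 50/1000 s/mm². The clinical in-plane pixel size is not pinned by any
  published protocol value and is exposed as configuration.

## QC metrics

For a repeated ROI measurement with per-repeat means m_i:
μ_R = mean(m_i), σ_R = sample SD(m_i);

* CV_R = 100·σ_R/μ_R (%); RC_R = 2.77·σ_R — the literal conventional constant,
  not 1.96·√2;
* bias = μ − DC_true, %bias = 100·(μ − DC_true)/DC_true with
  DC_true = 1.1 × 10⁻³ mm²/s for 0 °C water;
* noise estimate = 100·σ/μ within a single ROI (reported as the mean over
  repeats);
* b-value dependence = 100·|(ADC_b2 − ADC_b1)/ADC_b1| comparing the b0–b600
  and b0–b800 maps (asymmetric by construction: the lower-b map is the
  denominator);
* SNR_nDyn = spatial mean of the temporal-mean image over the ROI divided by
  the spatial mean of the temporal-SD image, from ≥ 2 (default 4) b=0 repeats.

Sample (n−1) SDs are used everywhere. Formulas are implemented literally: no
c4 small-sample SD-bias correction is applied (the c4-aware expectation
appears only in test tolerances). Claim thresholds (defaults CV_R < 1.5 %,
RC_R < 1.5 × 10⁻⁵ mm²/s, |bias| < 3.6 %, noise < 2 %, b-dependence < 2 %,
SNR ≥ 50) are compared strictly; boundary equality fails. On noiseless data
the temporal noise image is identically zero and SNR is reported as
*undefined* (not infinite, not failed).

Pearson correlations use the product-moment formula with Fisher-z 95 %
confidence intervals.

## ROI geometry

A voxel belongs to an ROI iff its centre lies *strictly* inside the boundary.
This rule is deterministic, translation-consistent, and matches common viewer
behaviour; boundary ties are excluded because they are measure-zero for
generic centres and make selections reproducible across platforms. No
partial-voxel weighting is applied — a 25-mm circle on a 2-mm grid centred on
a voxel centre selects exactly 121 voxels (console software sometimes reports
slightly different counts, e.g. 123, under unknown conventions; no standard
centre rule reproduces such counts and none is hard-coded).

## Sphere analyses

VOI diameters follow the 80 %-of-sphere rule, rounded to whole mm (as VOI
tools quantise) and floored at 10 mm — below that too few voxels sample the
VOI (the sampling limit at which the observed error behaviour becomes
non-monotonic). Repeat maps are averaged before relative errors are formed;
CV across repeats uses the CV_R formula.

The default study applies a **half-slice (2.5 mm) VOI centring offset along
z**. Hand-placed VOIs are centred visually on a 5-mm slice stack, so a
placement uncertainty of about half the slice spacing is inherent to the
measurement. This matters: with mathematically perfect centring on
slice-aligned spheres, the 80 % VOIs of the ≥ 17-mm spheres contain *no*
boundary voxels at all on the clinical grid and the noiseless partial-volume
error is identically zero — an artefact of idealised geometry, not a property
of the measurement being emulated. With the offset, noiseless errors are
≈ 1.6/1.4/0.25 % for the 17/22/28-mm spheres and vanish when the background
contrast is removed. The concentric (pure VOI-size) study deliberately uses
the true sphere centre, since its purpose is a clean-interior control.

## Reader study and agreement statistics

Per node, one true ADC ~ N(0.87 × 10⁻³, 0.12 × 10⁻³) mm²/s (truncated at 0)
and one true volume ~ N(1.0, 0.5) cm³ are drawn. Each reader×session
measurement is the mean of n voxel draws (n from the segmented volume at
32 voxels/cm³, the clinical voxel size), where each voxel is, with the
reader's contamination probability f, a draw from the surround distribution
(default N(1.74 × 10⁻³, 0.3 × 10⁻³) — the bright heterogeneous tissue around
nodes) instead of the node distribution (within-node SD 0.1 × 10⁻³); a
zero-mean Gaussian measurement error (SD 0.03 × 10⁻³ mm²/s) is added, and
volumes get reader scale factors (defaults 1.18 and 1.92, a conservative
senior and an over-segmenting junior reader) with a 10 % lognormal
per-session jitter. Defaults give 13 subjects, 54 nodes, ≥ 4 nodes each.
Reader 2's default contamination (f ≈ 0.057) is the analytic solution for an
expected inter-reader relative bias of −5.5 %; `with_inter_reader_bias()`
retargets it (positive targets contaminate reader 1 instead).

Agreement: differences are reader 1 − reader 2 (readers averaged over their
sessions) or session 1 − session 2 within reader; the relative scale uses the
pair mean as denominator, the standard Bland–Altman choice for ratio-scale
data. Limits of agreement are bias ± 1.96·SD (sample SD). Nodes are treated
as independent units, as an n = 54 analysis implies.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and
computes the exact two-sided null by subset-sum dynamic programming for
n ≤ 25 (equivalent to enumerating all 2ⁿ sign patterns, which the tests do
independently); above that, a normal approximation with tie and continuity
corrections. At least 5 non-zero differences are required.

The **meaningful-change range** is a reconstruction: the intra-observer LoA
half-width h (%) is the repeatability of one measurement, a longitudinal
change involves two, hence c = √2·h/100; treating c as a symmetric log-scale
limit gives the asymmetric range [100·(e^(−c) − 1), 100·(e^(c) − 1)] (e.g.
LoA [−9.2 %, 10.4 %] → [−12.9 %, +14.9 %]). The method label on the result
records that this is a reconstruction; the exact published computation it
emulates is not fully specified, so the formula is isolated behind one
function.

## What the synthetic world does not establish

The generators emulate the *statistical structure* of the analyses: known
true ADC, repeats differing only by noise, a smooth multiplicative spatial
bias, signal-domain partial volume, and contamination-driven reader
disagreement. They do not model EPI distortion, eddy currents, motion,
T2 shine-through, temperature drift, or scanner-specific reconstruction
filters. A green QC test here validates the *computations* — metric
formulas, geometry, statistics — not any particular scanner; measured QC
values from real hardware (e.g. a particular system's noise levels or its
Table of measured claims) are intentionally not reproduced.

## Numerical choices

* Float64 throughout; NIfTI written as float64, so file round trips are
  lossless.
* Bias-field fits use `numpy.linalg.lstsq`; exactly determined profiles are
  reproduced to machine precision.
* Truncated normals use rejection sampling (exact, negligible rejection rates
  at the default parameters).
* Degenerate inputs fail loudly with typed exceptions: empty ROIs, all-zero
  temporal noise (undefined SNR), all-zero paired differences, overlapping
  primitives, non-monotone b-values.
* Seeds: every generator takes one seed; repeats use `SeedSequence.spawn`
  streams, so adding repeats never perturbs earlier ones.
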