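# dwiqc

Quality control and reliability analysis of **apparent diffusion coefficient
(ADC)** measurements in diffusion-weighted MRI (DWI).

ADC is a promising quantitative imaging biomarker in oncology, but its
reliability is limited by scanner noise, gradient-field nonlinearity, partial
volume effects on small targets, and observer segmentation variability.
`dwiqc` implements the complete quantitative toolchain used to characterise
these error sources — with synthetic phantoms, so every analysis runs with no
scanner and no data download:

* **Synthetic phantoms** (`dwiqc.synth`, `dwiqc.readerstudy`): a 0 °C
  ice-water QC phantom with known true ADC (1.1 × 10⁻³ mm²/s), a six-sphere
  partial-volume phantom (diameters 10–37 mm), a polynomial multiplicative
  gradient-nonlinearity bias field, Rician noise, repeated acquisitions, and a
  simulated two-reader lymph-node measurement study with a segmentation
  contamination model.
* **ADC mapping** (`dwiqc.adc`): the two-b-value closed form
  `ADC = ln(S(b₁)/S(b₂)) / (b₂ − b₁)` and a multi-b log-linear fit, with
  low-signal masking as scanner consoles apply.
* **QC metrics** (`dwiqc.qc`): repeatability CV_R = 100·σ_R/μ_R and
  RC_R = 2.77·σ_R, ADC bias against the reference value, within-ROI noise
  estimate 100·σ/μ, b-value dependence, temporal SNR from repeated b=0
  dynamics, and pass/fail judgement against published claim thresholds.
* **Spatial bias profiling** (`dwiqc.roi`, `dwiqc.qc`): shifted-ROI series
  along an axis, relative error versus the isocentre, Pearson correlation with
  distance.
* **Sphere analyses** (`dwiqc.spheres`): per-sphere 80 %-diameter VOI scaling
  study, concentric VOIs in the largest sphere, and same-size differential
  VOI comparisons that isolate pure partial-volume contamination.
* **Observer agreement** (`dwiqc.agreement`): Bland–Altman bias and limits of
  agreement (bias ± 1.96·SD of paired differences, absolute or relative with
  pair-mean denominator), a tie-aware exact Wilcoxon signed-rank test, and a
  log-symmetric meaningful-change range derived from intra-observer limits of
  agreement.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from dwiqc.pipelines import run_icewater_qc, run_reader_study
from dwiqc.readerstudy import ReaderStudyConfig

res = run_icewater_qc(seed=1, noise_sd=30.0, n_repeats=4)
for p in res.report.pairs:
    print(f"b-pair {tuple(int(b) for b in p.b_pair)}: CV_R={p.cv_r:.2f}%  "
          f"bias={p.bias_pct:+.2f}%  noise={p.noise_pct:.1f}%  "
          f"pass={all(p.passes.values())}")
print(f"b-dependence = {res.report.b_dependence_pct:.2f}%  "
      f"SNR_nDyn = {res.report.snr:.1f}  all_pass = {res.report.all_pass}")

study = run_reader_study(ReaderStudyConfig(seed=1))
i = study.inter_reader
print(f"inter-reader: bias {i.bias:+.1f}% LoA [{i.loa_low:.1f}, {i.loa_high:.1f}]")
m = study.meaningful_change
print(f"meaningful change: [{m.lower_pct:+.1f}%, {m.upper_pct:+.1f}%]")
```

prints

```
b-pair (0, 100): CV_R=3.13%  bias=+0.29%  noise=39.0%  pass=False
b-pair (0, 600): CV_R=1.55%  bias=+2.37%  noise=10.1%  pass=False
b-pair (0, 800): CV_R=2.07%  bias=+1.07%  noise=8.9%  pass=False
b-dependence = 1.27%  SNR_nDyn = 35.7  all_pass = False
inter-reader: bias -6.0% LoA [-16.3, 4.3]
meaningful change: [-13.9%, +16.1%]
```

Reading the output: at this noise level (Rician σ = 30 signal units against
S₀ = 1000) the accuracy of the water ADC is fine (bias ≈ 1–2 %, true value
1.1 × 10⁻³ mm²/s), but the within-ROI noise estimate fails the < 2 % claim at
every b-pair — worst for the b0–b100 map, whose short b-range amplifies signal
noise into ADC noise. The simulated junior reader over-segments lymph nodes
into brighter surrounding tissue, producing a negative inter-reader
Bland–Altman bias; the intra-observer limits of agreement translate into an
asymmetric meaningful-change range: only relative ADC changes outside roughly
[−14 %, +16 %] should be read as real in a longitudinal study under these
conditions.

A command-line interface chains the same stages on files
(NIfTI + FSL-style `.bval`, YAML configs, CSV/JSON reports):

```bash
dwiqc simulate icewater --seed 1 --out sim/
dwiqc adc --in sim/icewater_rep0.nii.gz --bval sim/icewater_rep0.bval --pair 0 800 --out adc.nii.gz
dwiqc qc --series-dir sim/ --roi roi.yaml --out report.json
dwiqc spatial --map adc.nii.gz --axis y --step 20 --n 4 --diameter 22 --out profile.csv
dwiqc simulate readers --seed 1 --out rs/ && dwiqc agreement --table rs/readers.csv --out agree.json
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the headline
quantities of the reliability analysis: the differential same-size VOI
relative errors and the sphere scaling errors from their repeat-averaged mean
ADC inputs, and the Pearson correlations of the horizontal/vertical
spatial-bias profiles — and exercises the full synthetic pipeline
(ice-water QC, sphere study, reader study) end to end:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
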