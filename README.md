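# hpflux

Simulation and analysis of hyperpolarized [1-¹³C]pyruvate chemical-shift
imaging (CSI) for tumor treatment-response assessment with the
lactate-to-bicarbonate ratio.

## The problem

Hyperpolarized [1-¹³C]pyruvate MRI watches pyruvate convert in vivo to
¹³C-lactate (LDH, glycolysis) and ¹³C-bicarbonate (PDH → CO₂ → HCO₃⁻,
oxidative phosphorylation). The **Lac/Bic ratio** therefore indexes the
glycolysis/OXPHOS balance — the Warburg shift — and its 48-hour change
after anti-VEGF therapy predicts long-term survival in a C6-glioma rat
model: responders show a Lac/Bic *decrease*, non-responders an
*increase*. Raw data from such longitudinal animal experiments are rarely
public, so this package makes the entire analysis exercisable end to
end on synthetic data with the same statistical structure:

1. **kinetics** — three-pool dynamics `dP/dt = u(t) − (r₁ₚ + k_PL + k_PB + ρ)P`,
   `dL/dt = k_PL P − (r₁ₗ + ρ)L`, `dB/dt = k_PB P − (r₁ᵦ + ρ)B` with a
   gamma-variate input u(t) and RF-sampling loss ρ = −ln(cos θ)/TR,
   calibrated so Pyr/Lac/Bic peak at 20/28/33 s after injection;
2. **phantom** — two-ellipse digital rat brain (tumor Lac/Bic ≈ 11,
   normal ≈ 6), 16×16 phase-encoded FID CSI forward model (64 mm FOV,
   TR 75 ms, 5000 Hz, 256 samples) with Lorentzian lines, per-dataset
   zero-order phase and complex Gaussian k-space noise, plus a cohort
   generator (6 deceased / 7 survivors / 12 controls, survival
   13.5 ± 0.7 d mean ± SE, censoring at day 70);
3. **recon** — 15 Hz line broadening, 4× spectral zero-filling and 4×
   spatial k-space zero-padding (4 mm → 1 mm grid), per-voxel zero-order
   phasing, absorption-mode peak integration;
4. **quantify** — ROI ratios (ratio of sums), response direction,
   Gd-style tumor volumes and growth rates;
5. **stats** — exact Clopper–Pearson intervals, sensitivity/specificity,
   Wilcoxon signed-rank (exact for n ≤ 12), Kaplan–Meier and log-rank,
   Pearson correlation, cohort summary tables;
6. **pipeline / cli** — one reproducible, seeded experiment.

## Worked example

Run the full synthetic experiment (cohort → classification → survival
statistics) with one command:

```bash
hpflux run --seed 17 --out demo/
```

prints

```json
{
  "out": "demo/",
  "n_animals": 25,
  "sensitivity": 1.0,
  "specificity": 1.0,
  "logrank_p": 0.0004598699288482673
}
```

Reading: of the 13 treated animals, every one whose 48-hr tumor Lac/Bic
*increased* died before day 70 and every one whose ratio *decreased*
survived to censoring, so the biomarker classifies response perfectly
in this draw (sensitivity and specificity 1.0, exact 95% CIs in
`demo/report.json`), and the Kaplan–Meier curves of the
increase vs decrease arms separate with log-rank p ≈ 5 × 10⁻⁴. The
report also carries the cohort-wide correlation between tumor growth
rate and the 48-hr Lac/Bic (here r ≈ 0.73). `demo/` contains the
cohort CSV, a Table-1-style summary (mean ± SE per group), the KM
curves and the JSON report; add `--csi-animals 2` to also synthesize,
write (HDF5) and reconstruct (NIfTI maps) the imaging sessions of the
first two animals.

The dynamic-acquisition analysis behind the 19 s imaging-window choice:

```bash
hpflux fig1
```

```json
{
  "peak_times_s": {"pyr": 20.1, "lac": 28.1, "bic": 33.1},
  "window_start_s": 20.8,
  "window_duration_s": 19.0,
  "ratio_cv": {"lac_bic": 0.38, "lac_pyr": 0.49, "bic_pyr": 0.83}
}
```

i.e. the three metabolites peak at 20/28/33 s, the integral-maximizing
19 s window starts ~20 s after injection, and over the following 40 s
the Lac/Bic ratio is markedly more stable (lower CV) than either
pyruvate-normalized ratio — the property that makes Lac/Bic robust to
imaging-window timing.

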