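# Methods

This note documents the models, numerical conventions and design
choices behind hpflux, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Kinetic model

The dynamic slice-FID experiment is modeled as a unidirectional
precursor–product system driven by a gamma-variate arterial input:

    u(t)  = A ((t−t₀)/β)^α exp(−(t−t₀)/β),  t > t₀
    dP/dt = u(t) − (r₁ₚ + k_PL + k_PB + ρ) P
    dL/dt = k_PL P − (r₁ₗ + ρ) L
    dB/dt = k_PB P − (r₁ᵦ + ρ) B

with hyperpolarized magnetization non-recoverable, so each pool decays
with an effective longitudinal rate plus the RF-sampling loss
ρ = −ln(cos θ)/TR (continuous-rate approximation of the discrete
sawtooth; at θ = 10°, TR = 3 s the approximation error is below 2%).
Backward exchange, vascular/extravascular compartments and Bloch-level
RF simulation are deliberately out of scope: the model is a synthetic
stand-in for the measured dynamics, not a fitting tool, and no rates
are ever fit to data anywhere in the package.

Defaults (units s, 1/s, degrees): t₀ = 8, α = 2.0, β = 3.0,
k_PL = 0.06, k_PB = 0.006, r₁ₚ = 1/30, r₁ₗ = 1/10, r₁ᵦ = 1/26,
θ = 10, TR = 3. The conversion and relaxation rates were calibrated
once so the three signal curves peak at 20.1 / 28.1 / 33.1 s after the
start of injection, the ordering and timing observed in vivo in rat
brain. r₁ₗ and r₁ᵦ are *effective* decay rates lumping T₁ with
metabolic consumption and efflux; reproducing a lactate peak 5 s before
the bicarbonate peak in a common-precursor model forces the lactate
pool to decay faster, which is why r₁ₗ (1/10) is well above a pure-T₁
value. A consequence worth knowing: over a 40 s window starting at the
chosen imaging-window start (≈20 s) the Lac/Bic ratio has the smallest
coefficient of variation of the three ratios, but over windows anchored
at the *lactate peak* the model's Lac/Bic drifts (the two downstream
pools decay at different rates), so the stability analysis in
`fig1_analysis` uses the imaging-window anchor.

Integration uses LSODA with rtol 1e-8 / atol 1e-12; tests verify
against a dt = 1 ms explicit-Euler oracle (relative error < 1e-4 on
random parameter sets) and mass balance against the closed-form
incomplete-gamma integral of u(t).

## Phantom and forward model

The phantom is a single 5 mm axial slice: a brain ellipse
(semi-axes 22 × 18 mm) containing a tumor ellipse (9 × 7 mm, ~13 native
voxels) on the 16×16 / 64 mm grid. Per-tissue metabolite amplitudes
are mean-preserving lognormal draws (CV 0.10) around: Pyr 1.0
everywhere, Lac 0.46 (tumor) / 0.52 (normal), Bic chosen to put the
tissue Lac/Bic at 11.1 (tumor) and 6.2 (normal) — the scale reported
for this glioma model. Chemical shifts: Pyr 171.0 ppm (carrier),
Lac 183.2, pyruvate-hydrate 179.5, alanine 176.6, Bic 161.0 at
f₀ = 32.13 MHz (3 T). Linewidths default to 12 Hz (≈0.4 ppm,
well-shimmed); hydrate/alanine are off by default. Each dataset draws
one global zero-order phase offset, uniform over ±180°.

k-space is the unitary DC-centered 2-D DFT of the voxel image at each
FID sample plus i.i.d. circular complex Gaussian noise. SNR is defined
as the noiseless tumor-voxel pyruvate spectral peak height over the
spectral noise sd after the standard reconstruction;
`kspace_noise_sd_for_snr` propagates this analytically through the
linear chain (verified against Monte Carlo within a few percent).
Hyperpolarization decay across the 19.2 s encode train is not modeled
(signal amplitudes are frozen for the acquisition), matching the
processing model downstream.

What the phantom does **not** emulate: realistic anatomy, B₀
inhomogeneity, chemical-shift displacement, coil sensitivity, k-space
ordering effects, or motion. Passing recovery tests therefore bound
only the reconstruction and quantification arithmetic, not in vivo
robustness.

## Reconstruction

Pipeline per dataset: 15 Hz Lorentzian apodization → symmetric k-space
zero-padding to 64×64 with unitary inverse FFT (sinc interpolation,
1 mm grid; the PSF is the 16-point Dirichlet kernel, whose first axial
sidelobe is 21.5% of the peak — relevant for small-ROI partial-volume
effects) → per-voxel spectral FFT with 4× zero-filling (1024 bins) →
zero-order phasing → absorption-mode window integration.

Spectral normalization: S(f) = 2·Δt·DFT(fid with first point halved).
Halving the first point is the standard trapezoid correction; without
it a one-sided FID spreads a flat pedestal across the spectrum that,
at Bic/Pyr ≈ 0.04, contributes about half of the bicarbonate window
area. The factor 2 makes the absorption area of a Lorentzian of
amplitude A equal A times the analytic in-window fraction
(2/π)·arctan(2w/FWHM), independent of zero-filling.

Zero-order phase: the phase maximizing the real-part integral over a
window has the closed form φ = arg(∫ window S df); hpflux uses it
directly (exact maximizer of the same objective a numeric search would
optimize). In `reconstruct_maps` every peak of a voxel is phased by
default with the estimate from that voxel's strongest peak
(`phase_mode="reference"`): a zero-order offset is frequency
independent, and self-phasing a weak peak locks onto noise (a
magnitude-like positive bias) and onto the dispersion tail of the
large pyruvate resonance, which near bicarbonate exceeds the Bic peak's
own area. Per-peak self-phasing with a low-SNR fallback remains
available (`phase_mode="per-peak"`); the standalone
`estimate_zero_order_phase` flags low-signal windows and falls back to
φ = 0. At spectral peak SNR 10 the phase estimate from a single line
has ~5° error sd (close to the information bound); tests assert ±0.5°
recovery in clean constructed cases and Monte-Carlo bounds at SNR 10
and 50.

Integration windows default to 0.5 ppm halfwidth. The window is a
compromise: equal capture fraction for all metabolites (equal
linewidths) cancels in every ratio, while pickup of the pyruvate
absorption tail grows with window width and would bias Bic by >15% at
1.5 ppm halfwidth. The residual tail is removed in closed form:
integrals over two nested windows on the reference line determine its
amplitude and half-width γ by arctan inversion (no lineshape fitting),
and the predicted 1/Δ² tail inside each other window is subtracted.
Negative areas are clamped to zero in the released maps (with counts in
provenance) but the unclamped areas are kept alongside: ROI sums use
them, because clamping censors the negative noise half and biases
low-SNR ROI sums upward.

## Quantification

ROI ratios are ratios of sums over the mask (robust to low-signal
voxels; a mean-of-voxel-ratios mode exists for comparison, and the two
coincide on uniform ROIs). Denominators below a floor flag the ratio
undefined rather than producing infinities. Tumor masks for recovery
experiments are the nearest-neighbour-upsampled tumor label eroded by
2 mm ("core ROI"), emulating manual ROIs drawn inside the lesion
border; with the full mask the 2× higher normal-brain bicarbonate
leaks into the ROI through the Dirichlet sidelobes and biases Lac/Bic
low by ~10–15%. A spatial Hamming window would suppress the sidelobes
but broadens the main lobe enough to worsen the mixing for a
~2-native-voxel tumor, and is not applied. At these study conditions
(SNR 20 on pyruvate) the tumor-core Bic ROI sum has single-digit SNR,
so a single session's Lac/Bic carries ~20–25% noise — bicarbonate is
genuinely the SNR-limiting metabolite in this kind of experiment;
recovery is therefore assessed as a 20-replicate mean. Tumor volume is voxel counting times voxel volume
across slices; growth rate is the post/baseline volume quotient.

## Cohort generator and statistics

Each group (deceased n = 6, survivor n = 7, control n = 12) draws
baseline tumor and normal-brain ratios from truncated normals on the
reported scale (sd = SE·√n), applies its multiplicative 48-hr effect
(tumor Lac/Bic: ×1.60 deceased, ×0.82 survivor, ×1.26 control) with
lognormal jitter (σ = 0.12, keeping ≥90% of survivors decreasing and
≥90% of deceased increasing while allowing occasional discordant
animals). Deceased survival is Normal(13.5, 1.7) truncated at 1 day
and rounded; animals alive at day 70 are censored there; controls draw
from the deceased distribution (their survival is not reported;
untreated C6 gliomas are uniformly fatal). Tumor growth anchors to the
group-mean growth quotients (1.59 / 1.08 / 1.30) with a within-cohort
coupling of 0.04 per Lac/Bic unit and residual sd 0.16, which centers
the cohort-wide Pearson correlation between growth rate and 48-hr
Lac/Bic near 0.77 (single-seed values at n = 25 scatter by ~±0.15).

Statistics follow the study design: exact Clopper–Pearson intervals
(beta-quantile inversion; k = 0 and k = n boundaries handled exactly);
sensitivity/specificity with "death before day 70" as the positive
class and "48-hr Lac/Bic increase" as a positive test; Wilcoxon
signed-rank with zero differences dropped, midranks for ties, exact
sign-flip enumeration for n ≤ 12 and a tie-corrected normal
approximation otherwise (two-sided p as twice the smaller tail, capped
at 1); Kaplan–Meier and log-rank via lifelines with deaths preceding
censorings at tied times; p-values floored at the smallest positive
double, never reported as 0. No multiple-testing correction and no
multivariable survival modeling are applied.

## Reproducibility

Every stochastic step takes an explicit seed; the experiment driver
derives per-animal/timepoint seeds as
(master·1000003 + crc32(id|timepoint)) mod 2³¹, so extending a cohort
never perturbs existing draws. Identical configs produce
byte-identical cohort CSVs and report JSONs. Problem sizes used in the
shipped experiments: 16×16×256 CSI grids, 64×64×1024 reconstructions,
25-animal cohorts, 20-replicate recovery ensembles, 100-seed generator
surveys — sizes chosen to exercise every code path at full fidelity on
a laptop-class machine.

## Known limitations

- The kinetic model is phenomenological; its rates are not biological
  estimates and must not be compared to k_PL values from exchange
  fitting.
- Tail subtraction assumes a common Lorentzian lineshape; strong
  lineshape distortions (B₀ inhomogeneity) would defeat it.
- The phantom's tumor is large relative to the reported ~140 mm³
  volumes (one compact slice) so that the ROI contains enough native
  voxels for stable statistics; volumes in the cohort table are drawn
  independently of the imaging phantom.
- Sensitivity/specificity at n = 6/7 have very wide exact intervals;
  the generator reproduces the scale of the point estimates, not their
  sampling variability across hypothetical replications of the study.
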