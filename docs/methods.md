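# Methods

`mrsinet` implements an end-to-end pipeline for classifying brain-tumor
MR spectroscopic imaging (MRSI) voxels directly from raw time-domain
signals: a metabolite-basis simulator of free-induction decays (FIDs),
a two-block neural model (domain transformation followed by a densely
connected 1D classifier), an evaluation suite, and 1D Grad-CAM
saliency. This note records the model, its assumptions, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Spectral basis and signal model

Each of the 21 brain metabolites (Ala, Asp, Cr, GABA, Glc, Gln, Glu,
Gly, GPC, GPE, GSH, Ins, Lac, NAA, NAAG, PCh, PCr, PEtn, Ser, ScyIns,
Tau) is represented as a small set of Lorentzian lines at literature
chemical shifts with proton-count-weighted amplitudes, shipped as
`data/resonances.csv`. A noiseless metabolite FID is

    FID[t] = sum_lines a_l * exp(2*pi*i * f_l * t) * exp(-t / T2),

with `f_l = (ppm_l - 4.7) * gamma * B0` the offset from the water
carrier (proton gamma = 42.576 MHz/T) and intrinsic `T2 = 0.15 s`
(~2 Hz natural linewidth). Multiplets are collapsed to their centre
positions, so J-coupling evolution is **not** modelled and echo time
(35 ms default) is metadata only. This approximation preserves the
features the downstream model consumes — peak positions, relative
areas, linewidths — but not multiplet fine structure or TE-dependent
phase evolution (Lac inversion at intermediate TE, for example).

Sampling grid: 1024 complex points; spectral width 2000 Hz at 3 T,
scaled proportionally to field so the ppm span (~15.7 ppm) and hence
the ppm axis are field-invariant. A consequence worth knowing: the
per-sample phase advance of a line at fixed ppm is then identical at
every field, while decay envelopes (intrinsic T2 and line broadening in
Hz) occupy different fractions of the acquisition window — higher
fields yield narrower lines in ppm, as in real spectra. The carrier
sits at 4.7 ppm (water), so the residual water line of
non-water-suppressed acquisitions appears at offset 0 Hz.

## Simulation and augmentation

A simulated spectrum draws per-metabolite concentrations uniformly
within normal-adult-brain literature ranges (e.g. NAA 7.0–10.0, Cr
5.5–7.0, Lac 0.2–1.0 mmol/L) and composes the clean FID as the
concentration-weighted sum of basis FIDs. The *target* is the DFT of
that clean FID, fftshifted to ascending frequency, with the real and
imaginary channels independently min–max normalized to [0, 1]
(constant channels map to zeros and set a degenerate flag). The
*input* is the clean FID after augmentation, applied in a fixed order:

1. zero-order phase shift, uniform in [-pi/4, pi/4];
2. Lorentzian line broadening, uniform in [0, 40] Hz (exponential
   apodization `exp(-pi*lb*t)`; adds `lb` to every FWHM);
3. a global intensity scale (below);
4. optional residual water at 4.7 ppm, scaled relative to the creatine
   peak (off by default; the augmentation table does not include it);
5. additive white Gaussian noise, per-channel SD sigma uniform in
   [0.05, 1].

The target never depends on augmentation draws, making the learning
task simultaneous domain transformation and denoising. Field strength
is drawn per spectrum, uniform and continuous in [3, 7] T (a flag
restricts to the discrete endpoints).

**Noise calibration.** "Noise magnitude" is the per-channel Gaussian
SD. The intensity scale (0.03) was calibrated once so the
simulation-time SNR — the time-domain creatine signal amplitude over
sigma, `simulate.simulation_snr` — spans [0.94, 18.8] as sigma sweeps
its range, an interval containing the intended 1–3 regime at the noisy
end. The spectroscopic in-vivo SNR definition (creatine peak-to-peak
over the SD of the signal-free 8–9 ppm baseline) is a different
estimator with a pure-noise floor around 3 (the expected range of ~13
Gaussian bins divided by their SD); it is used for evaluation, never
for calibration.

**Two-class cohorts.** The glioma profile multiplies the healthy
concentration ranges by: GPC and PCh x3 (elevated total choline,
membrane turnover), NAA x0.4 (neuronal loss), Lac x4, Glu and Gln x1.5
(crowding the 2.25 ppm Glx/2-HG region). These factors are
configuration, not biological claims; they mirror the biomarker
directions radiologists use (Cho/NAA inversion in tumor). Labeled
datasets interleave the classes (per-round shuffled profile order) so
every contiguous train/validation/test slice stays balanced to within
one example per class; a global shuffle can leave a small test split
single-class, which breaks ROC evaluation.

**Splits and determinism.** Floor-based split sizes with the remainder
to train (50,000 at 0.8/0.1/0.1 gives exactly 40,000/5,000/5,000). All
randomness descends from one master seed through two spawned
generators (parameters, noise); noise is drawn in example order, so
chunked synthesis is bit-identical to unchunked. Inputs are stored
divided by one global scale (the largest first-sample channel value of
the train split), recorded in provenance; this keeps storage ranges
tame without touching per-example SNR.

**Phantom preset.** A 7-metabolite composition at fixed concentrations
(NAA 6, Glu 8, GABA 1, Cr 4, free choline 5, Ins 8, Lac 4 mmol/L)
emulates a physical quality-control phantom: degenerate concentration
ranges, so only field, phase, broadening and noise vary.

## The two network blocks

No deep-learning framework ships in this package's dependency set; the
networks run on a small reverse-mode autodiff engine (`mrsinet.nn`)
over numpy — tensors with gradients, im2col convolutions, batch norm,
Adam — whose gradients are verified against central finite differences
in the test suite. Float32 parameters and activations; losses
accumulate in float64.

**Transform block** (AUTOMAP-inspired, 1D): three fully connected
layers with tanh activation (default widths 1024/1024/1024 on the
flattened 2048-value complex FID), two stride-1 same-padding
convolutions with ReLU (64 channels, kernel 5 by default), and a
stride-1 transposed convolution back to the spectral channels. The
deconvolution is stride-1 because nothing in the block downsamples. By
default the real and imaginary output channels are produced by two
channel-wise instances sharing the architecture and training loop; a
single shared network with 2-channel output is a config switch
(`shared_channels`). Training: Adam, MSE loss, reference
hyperparameters lr 5e-6, batch 20, 200 epochs; best-validation weights
are returned, with optional early stopping (off by default). Inference
clips predictions to [0, 1], the normalized target convention (the
deconvolution head is unbounded).

**Classifier block** (DenseNet-style, 1D): a stem convolution, then
dense blocks (default 3 blocks x 4 layers, growth 16, kernel 3) whose
layers apply pre-activation batch-norm -> ReLU -> conv and concatenate
their output onto all preceding feature maps; transitions compress
channels by half (1x1 conv) and average-pool by two; final batch-norm,
ReLU, global average pooling and a linear head with sigmoid output.
The classifier consumes the transform block's spectral output inside
the combined graph; the user-facing input is always the raw FID.
Training: Adam on binary cross-entropy (reference lr 5e-5, batch 200,
100 epochs); the transform block is fine-tuned at 0.1x the classifier
learning rate by default, or frozen bitwise with
`fine_tune_transform=False`. Training refuses splits more imbalanced
than 60/40 unless explicitly allowed. Decision threshold 0.5,
configurable.

## Saliency

1D Grad-CAM over the feature maps of the last convolutional layer in
the final dense block (its own output channels, not the concatenated
block map; config-overridable by attribute path): channel weights are
the spatial means of the class-score
gradient, the map is `ReLU(sum_k alpha_k A_k)`, linearly interpolated
to the 1024-point ppm axis and max-normalized (all-zero maps skip
normalization). For the healthy class the gradient is taken with
respect to the negated glioma logit, so both classes yield
positive-evidence maps. Region reports average map importance inside
named ppm windows — tCho 3.1–3.3, NAA 1.9–2.1, Glx/2-HG 2.15–2.35, tCr
2.95–3.05 — and rank them descending, ties resolved by declaration
order. Linear (not nearest) interpolation matters for window means and
is therefore fixed and documented.

## Metrics

Reconstruction: MSE (and per-example RMSE = sqrt(MSE)), PSNR with peak
1 (spectra are [0,1]), and 1D SSIM with a Gaussian window (size 11,
sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1) — standard
image-SSIM constants adopted because no 1D convention exists; they are
recorded in every report. Classification: ROC over unique score
thresholds with trapezoidal AUC (ties handled as simultaneous
crossings, equivalent to mid-rank; verified exactly against a
brute-force concordant-pair count), and confusion counts with
sensitivity, specificity, accuracy and cell percentages to two
decimals. The spectroscopic creatine SNR is peak-to-peak of the real
channel in 2.9–3.1 ppm over the baseline SD in 8.0–9.0 ppm, flagged
infinite for an exactly flat baseline.

## Desk-scale training schedules

The reference hyperparameters above describe the full-scale regime
(50,000+ spectra). Tests and the acceptance script run a desk-scale
schedule chosen once (`mrsinet.presets`): 12,000 pairs, shared-channel
transform with the default FC widths but 16-channel convolutions, Adam
lr 1e-3, batch 64, 18 epochs (~6 minutes on one CPU); classifier at
600 examples per class, 3 blocks x 2 layers, growth 8, lr 1e-3, batch
50, 12 epochs. Problem sizes are stated in the README's worked
example.

**What desk scale achieves and what it does not.** At this schedule
the transform block reaches a held-out test MSE near 1.3e-3 overall:
about 2.6e-4 on the real (absorption) channel and 2.4e-3 on the
imaginary (dispersion) channel. The gap is structural, and worth
recording. Under per-spectrum, per-channel min–max normalization, the
dispersion channel's baseline level is set by the asymmetry of its two
extremes — an order-statistic functional of all 21 concentrations that
accounts for ~94% of that channel's example-to-example variance. An
optimal *linear* FID-to-spectrum map (ridge regression on 7,200
examples) achieves 1.5e-3 and cannot beat the per-bin mean on the
dispersion channel at all, so the trained network — which does beat
the linear bound — is genuinely learning nonlinear structure and is
limited by optimization steps (a few thousand at desk scale versus
hundreds of thousands in the full-scale regime), not by data. Min–max
renormalizing predictions does not help (the residual is not
channel-affine). Consequently the desk-scale mean MSE sits above the
full-scale regime's reported quality; the real-channel figure is the
desk-scale quantity comparable to it.

A caveat on attribution directionality: the synthetic glioma profile
makes the two classes' NAA concentration ranges fully disjoint while
their total-choline ranges overlap, so *reduced NAA* is — by
construction — at least as discriminative as elevated choline. A
well-trained classifier therefore splits its glioma evidence between
the NAA and tCho windows, and which of the two ranks first in the
glioma-class Grad-CAM report can be a near-tie that depends on
initialization. The healthy-class direction (NAA dominant) is stable.

## Synthetic cohorts vs real data

Passing results on the synthetic two-class task (AUC, saliency
directionality) demonstrate that the architecture, training loop and
explanation machinery behave correctly on a cohort whose class signal
is known by construction. They do not demonstrate clinical
performance: real MRSI voxels add scanner artifacts (eddy currents,
frequency drift, lipid contamination), macromolecule baselines,
partial-volume mixtures, J-coupled multiplet structure and
between-patient variability, none of which the simulator models.

## Degenerate inputs and numerical conventions

Constant spectral channels normalize to zeros with a degenerate flag
rather than NaN. Zero-noise, zero-broadening, zero-phase augmentation
operators are exact no-ops. Probabilities are clipped to
[1e-7, 1 - 1e-7] inside the BCE metric; training uses a numerically
stable logits formulation. PSNR of an exact reconstruction and SNR of
an exactly flat baseline are reported as infinite with a flag.
Checkpoints are NPZ archives of named arrays plus a JSON header;
datasets are HDF5 (one file per split: `fids`, `targets`, optional
`labels`, `ppm_axis`, JSON provenance attribute) with an NPZ fallback
of identical keys. Stage re-runs skip work when the stored
configuration hash matches.
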