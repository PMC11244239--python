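# Methods

`strokeeg` implements an EEG-based ischemic-stroke detector built from
three components: phase-lag-index (PLI) functional connectivity with a
group-derived correlation weighting (cwPLI), per-channel sample entropy
(SaEn), and an image classifier (a VGG-16-shape network with
squeeze-and-excitation blocks, "MSE-VGG"). This note records the models,
the parameter choices, and the places where the design was genuinely
open.

## Signal model and preprocessing

Recordings are 19-channel scalp EEG in the international 10-20 montage,
sampled at 256 Hz. Preprocessing is:

1. **Band-pass 1-35 Hz**, zero-phase (forward-backward) Butterworth of
   order 8 (16 poles as a band-pass). The band keeps the clinical
   delta/theta/alpha/beta range and suppresses 50 Hz mains interference;
   the two-pass magnitude at 50 Hz is below -60 dB. Zero-phase filtering
   matters because any filter-induced lag would bias the phase statistics
   downstream. An order-4 band-pass leaves 50 Hz at only about -31 dB
   after two passes, which is why order 8 is the default. Edge
   transients decay on the ~1 s time scale of the 1 Hz high-pass edge;
   they are unavoidable for finite recordings and are the reason
   filtering is applied to the continuous record before segmentation.
2. **Bad-channel repair** by inverse-distance weighting of the 4 nearest
   good electrodes on the unit sphere. Electrode coordinates are
   computed from the 10-20 placement rules themselves (circumferential
   ring at 36-degree azimuth steps, midline/coronal arcs at 20% arc
   steps, great-circle midpoints for F3/F4/P3/P4). A full spherical-
   spline interpolation would be an acceptable drop-in alternative; IDW
   was chosen because it is exactly testable (a convex combination of
   equal channels reproduces the common value).
3. **Segmentation** into 1-second non-overlapping epochs (256 samples);
   the trailing remainder is discarded.
4. **Artifact screening**: epochs whose peak absolute amplitude exceeds
   100 uV are dropped. This replaces manual artifact review with a
   reproducible rule; it will not catch low-amplitude EMG.

## Connectivity: PLI and cwPLI

For an epoch, each channel's instantaneous phase is the angle of its
analytic (Hilbert) signal. For channels i, j with phase difference
`dphi(t)` wrapped to (-pi, pi],

    PLI_ij = | mean_t sign(dphi(t)) |  in [0, 1].

Zero-lag differences (|dphi| < 1e-9 rad) contribute sign 0, so
numerically identical channels give PLI exactly 0 — this is the property
that makes PLI insensitive to volume conduction. The per-epoch matrices
are symmetric with zero diagonal; the subject-level matrix is the mean
over that subject's epochs.

The correlation weight of a pair scores how consistently its PLI
separates the groups. With P stroke and M control subjects, over all
P x M cross-group subject pairs,

    w_ij = | n_greater - n_smaller | / (P * M),

where `n_greater` counts comparisons with stroke PLI_ij above the
control's and `n_smaller` the reverse; ties count for neither. Weights
lie in [0, 1], and cwPLI = PLI * w elementwise, so cwPLI never exceeds
PLI. **Leakage control:** weights are estimated on the training subjects
of each cross-validation fold only and then applied to held-out
subjects. Computing them on all subjects would leak test labels into the
features; whether to compute weights per fold was an open design choice
and the leakage-safe variant was chosen.

## Complexity: sample entropy

SaEn(m, r) = -ln(A/B), where B counts ordered template pairs of length
m within Chebyshev distance r and A the same at length m+1; template
start positions run over the same K-m indices at both lengths
(Richman-Moorman convention) and self-matches are excluded. Defaults are
the EEG field standard m = 2, r = 0.2 x SD of the epoch; with the
SD-relative radius the estimate is amplitude-scale invariant. Degenerate
cases: a constant epoch returns 0 (perfectly regular); when no template
pair matches at either length the value is undefined and is capped at
ln(K - m) with a warning so feature maps stay finite.

## Fusion and image encoding

The cwPLI matrix occupies the off-diagonal cells; the SaEn vector,
min-max rescaled to [0, 1] with bounds computed on training data only,
occupies the otherwise information-free diagonal. The fused 19 x 19
matrix is quantized through a fixed 256-entry blue-to-yellow colormap
(entries forced distinct so a rendered image decodes back to the
quantized matrix exactly) and upscaled nearest-neighbor to the
classifier's input size. Fusion and rendering never see class labels.
The exact fusion layout and colormap were open choices; the diagonal
placement preserves the square matrix shape losslessly, and an
alternative extra-row layout was considered and rejected because it
breaks the square-input assumption of the backbone.

## Classifier: MSE-VGG

A VGG-16-shape backbone — 13 convolutional layers (all 3x3, stride 1,
same padding, ReLU), 5 max-pool stages, 3 fully connected layers — with
one squeeze-and-excitation (SE) block after each pooling stage. An SE
block computes the per-channel spatial mean (squeeze), passes it through
a two-layer gate (ReLU inner layer of width max(1, C/r), sigmoid outer
layer; reduction r = 16 by default, the SE-origin convention), and
rescales each channel by the resulting scalar in (0, 1), so the output
magnitude never exceeds the input's. Gate biases are enabled. The final
SE block sits before flattening (its natural place while the tensor is
still spatial; the alternative was unspecified). `se_enabled=False`
builds the plain-VGG ablation with an identical census otherwise.

The network, its initialization (He-normal, seeded) and the SGD training
loop are implemented in NumPy with im2col convolutions; gradients are
validated against finite differences in the test suite.

### Training protocol

Full-scale defaults: SGD, batch 512, learning rate 1e-4, up to 100
epochs, cross-entropy loss, early stopping on a validation split (10% of
training subjects, at least one per class) with patience 10, restoring
the best-validation weights. Every random element (cohort, folds,
initialization, shuffling) derives from one pipeline seed, so reruns are
byte-identical.

Desk scale (the configuration exercised by the tests and the acceptance
study) uses 32 x 32 inputs, a 1/16 width multiplier (stage widths
4/8/16/32/32, FC width 256), batch 64, learning rate 0.03 with momentum
0.9 and a 0.85 per-epoch decay, at most 12 epochs with patience 4, and a
training-loss floor of 0.08 as a convergence stop. Inputs are
standardized per color channel with training-split statistics. These
choices were tuned for reliable convergence of the narrow desk-scale
network: with few hundreds of training images, large batches give too
few SGD steps per epoch and the loss can sit on its initial symmetric
plateau (cross-entropy ~ln 2, tiny logits, often already-good ranking)
for many epochs; smaller batches with momentum and decay break the
plateau reliably. As a final guard against the initialization lottery,
the cross-validation driver retrains a fold up to twice with fresh
seeded initializations when the training loss never leaves the plateau
(threshold 0.55); the retry decision uses training loss only, so no
held-out information is involved. The protocol was chosen for
convergence behavior, not for any particular accuracy value.

## Evaluation

Cross-validation is stratified at the **subject** level: all epochs of a
subject share a fold, every subject is tested once. Per fold the
confusion counts give Acc = (TP+TN)/total, Sen = TP/(TP+FN),
Spe = TN/(TN+FP) (percentages; undefined when a denominator is zero),
and AUC is the rank-statistic (Mann-Whitney) form with midranks for
ties, with the softmax probability of the stroke class as score. An
epoch-level split mode exists only as an explicitly named leakage-prone
option for comparison.

## Synthetic cohorts

The study dataset is private, so a generator produces two-class cohorts
with the two effects the pipeline exploits. Per channel,

    x_c(t) = A g_c [ sqrt(k_c) Re(e^{i lag_c} Z(t)) + sqrt(1-k_c) Re(Z_c(t)) ]
             + pink(t) + complexity * broadband_c(t) + sensor noise,

where `Z` is a subject-wide analytic sum of band-limited oscillators
(delta/theta/alpha/beta, alpha-dominant mixture), `Z_c` an independent
copy per channel, and `lag_c` fixed per-channel phase lags (evenly
spaced on (0.1, pi-0.1), fixed-seed permutation) so that coupled
channels have nonzero, constant pairwise lags — the signature PLI
detects. All noise terms are band-limited to 1-35 Hz.

Structure of the coupling fraction `k_c`:

* **Class effect.** A fixed subset of half the channels is "affected":
  their base coupling is 0.6 for controls and 0.3 for stroke subjects
  (controls more synchronized). The remaining channels keep the
  class-independent mean level 0.45 — an ischemic lesion perturbs part
  of the network, not all of it.
* **Confound.** The unaffected channels' coupling varies strongly
  between subjects (SD 0.16) but identically for both classes:
  subject-specific synchrony that carries no diagnostic information.
  These are exactly the connections the correlation weighting exists to
  discount; with uniformly informative channels every weight saturates
  near 1 and cwPLI degenerates to PLI.
* **Spatial heterogeneity.** A fixed per-channel profile p_c in
  [0.35, 1] attenuates coupling as k_c = base^(1/p_c), preserving the
  endpoints 0 and 1 exactly (so a fully coupled, noise-free cohort still
  yields PLI = 1 for every pair).
* **Between-subject variability.** Affected channels' base coupling
  receives Gaussian jitter (SD 0.05) and the complexity scale a relative
  jitter (SD 0.08) per subject. Without jitter, same-class subjects are
  near-clones and standardized group gaps reach a biologically absurd
  20-45 pooled SDs. The jitter magnitudes were calibrated so the
  cross-validated accuracies of the three feature families land in the
  mid-80s-to-low-90s band that clinical EEG stroke classification
  reports, with plain PLI the weakest and the fusion feature the
  strongest — the regime the weighting and fusion mechanisms target.

Complexity: the entropy dial scales a flat-spectrum 1-35 Hz component
(6 uV at scale 1) on top of a fixed 1/f background (5 uV); flat
broadband noise is what actually raises sample entropy (a 1/f term of
equal power barely moves it). Defaults: complexity 1.0 (control) vs 1.5
(stroke); the direction and size are a design choice — the source data
offer no quantitative anchor for the complexity effect.

What the generator does **not** emulate: physiological lesion geometry,
EOG/EMG artifacts, electrode drift, volume-conduction mixing, non-
stationarity within a recording, and realistic age/medication
heterogeneity. Passing end-to-end tests therefore shows that the
pipeline recovers the two constructed effects under realistic noise and
subject variability — not that it would reach the same numbers on
clinical data.

## Problem sizes used in tests

The end-to-end study uses 10 + 10 subjects at 60 s each (1,200 one-second
epochs), subject-level 5-fold cross-validation, three feature families
(PLI, cwPLI, cwPLI+SaEn) and three cohort seeds, with the desk-scale
classifier; property tests use shorter recordings (8-20 s) and 10 seeds
per claim. These sizes were chosen so the whole suite runs comfortably
on a single CPU while keeping every statistical claim at the stated seed
counts.

## Known limitations

* The EDF writer is minimal (16-bit, 1-s records, integer sampling
  rates); it is validated against an independent reader but does not
  support annotations or discontinuous records.
* Sample entropy on 256-sample epochs is a high-variance estimator; the
  fusion feature inherits that variance.
* The desk-scale network is narrow; occasional training runs stay on the
  loss plateau for several epochs, which early stopping with
  best-weight restoration absorbs.
* With very small cohorts (2 subjects per class) the early-stopping
  validation split leaves little training data; the smoke configurations
  accept that trade-off.
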