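# Methods

This note documents the models, conventions and design choices behind
`fnirscad`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Signal model and preprocessing

Continuous-wave fNIRS measures optical density (OD) at two wavelengths
(780/850 nm here) per channel at 8.138 Hz. The chain to task-locked
hemoglobin responses is:

1. **Low-pass 0.5 Hz**, 6th-order Butterworth applied forward–backward
   (`sosfiltfilt`), i.e. zero phase with the design order quoted and an
   effective squared magnitude response. Edge handling uses even
   (reflective) padding of three design-orders of samples.
2. **Modified Beer–Lambert law.** Per sample and channel the 2×2 linear
   system `ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ)` is solved
   for (ΔHbO, ΔHbR) in µM, with source–detector distance d = 3 cm and
   DPF = 6.0 at both wavelengths (no partial-volume correction). The
   extinction coefficients are compiled values (Prahl's hemoglobin
   tabulation): ε(780) = (736.0, 1102.2), ε(850) = (1058.0, 691.32)
   cm⁻¹ M⁻¹, converted to µM units; the table is an explicit argument so
   an alternative compilation can be swapped in. Because the synthetic
   generator uses the same table for its forward projection, the
   round-trip is exact to machine precision; absolute concentration scale
   on real data depends on the chosen table and DPF.
3. **Band-pass 0.01–0.3 Hz**, same filter conventions, designed as a
   single band-pass (not cascaded high/low sections).
4. **Segmentation.** One segment per task onset, 246 samples long
   (the canonical input length; 30 s at 8.138 Hz rounds to 244 — the
   extra two samples keep the classifier input shape at the standard
   246 × 68 and start exactly at onset). Baseline is the mean over
   [−1, 0] s before onset, subtracted per channel; correction is
   idempotent. Segments are averaged element-wise.

## Vector-phase indicators

ΔCBV = (ΔHbO+ΔHbR)/2 and ΔCOE = (ΔHbO−ΔHbR)/2 are the volume/oxygen-
exchange axes of the vector analysis; |L| = √(ΔCBV²+ΔCOE²) is the vector
magnitude (equivalently √((ΔHbO²+ΔHbR²)/2)) and k = atan2(ΔCOE, ΔCBV)
the phase angle in (−π, π], with k(0, 0) := 0 so degenerate samples do
not propagate NaNs into the network. The first five indicators scale
linearly with the input; k is scale-invariant.

## Montage and channel embedding

The architecture depends only on one montage property: every channel has
exactly one left/right mirror partner. The default 68-channel montage is
a symmetric grid (rows of up to 9 positions per hemisphere) with pairs
found by x-sign reflection; a device-specific layout can be loaded from
CSV (`channel_id, x, y, hemisphere`), with midline channels assigned a
small offset toward their designated partner before import. The
*stacking order* interleaves left channels with their mirrors, so a
kernel-2/stride-2 depthwise convolution along the stacked axis spans one
symmetric pair per application; the next such layer merges adjacent
pair-units (17 groups of 2). The C3 ablation replaces the stacking with
a seed-controlled uniformly random permutation.

## Architectures

All variants are ensembles of six per-indicator branches with a shared
classification block (Dense 64 → ELU → Dense 16 → ELU → Dense 2 →
softmax). Hidden widths are a deliberately small funnel for cohorts of
order 10²; they are configurable. Branch layouts (valid padding
throughout; each convolution followed by batch norm and ELU in the
proposed family):

| variant | branch layers | per-branch output | flatten |
|---|---|---|---|
| proposed | DW-Conv1D 32/16 (time) → DW 2/2 (pairs) → DW 2/2 (pair-units) | 14 × 17 | 1,428 |
| C1 | DW-Conv1D 32/16 (time) | 14 × 68 | 5,712 |
| C2 | DW 2/2 → DW 2/2 (channels) → DW-Conv1D 32/16 (time) | 14 × 17 | 1,428 |
| C3 | proposed after channel shuffle | 14 × 17 | 1,428 |
| EEGNet | temporal conv (1,16)/(1,4) → spatial depthwise (68,1)×17 → pool (1,8)/(1,2) → separable (1,8) → pool (1,6) | 14 × 17 | 1,428 |
| ShallowConvNet | temporal conv (1,16)/(1,4) → spatial (68,1)×17 → square → pool (1,5)/(1,4) → log | 14 × 17 | 1,428 |

EEGNet's spatial stage is implemented as a full-height (68, 1) depthwise
kernel with 17 maps — the only kernel consistent with the published
stage-output shapes at this input size — with max-norm 1;
ShallowConvNet's two convolutions carry max-norm 2, and its batch norm
uses ε = 1e−5, momentum 0.1. Dropout p = 0.4 follows each flatten in the
proposed family and sits at the published positions inside the EEG-style
blocks.

The layers are a purpose-built numpy core with analytic backpropagation
(verified against central finite differences in the test suite), Glorot
uniform initialization from a single per-network generator, inverted
dropout, and the Adamax optimizer (β₁ = 0.9, β₂ = 0.999, ε = 1e−7).
Training is single-threaded float64, so fixed seeds give bit-identical
runs.

## Training recipe and evaluation

Leave-one-subject-out cross-validation: per fold the model is rebuilt
from the same seed, trained with weighted categorical cross-entropy
(class weights HC 0.9 / MDD 1.0), Adamax at learning rate 0.001, batch
size 32, and per-variant epochs (C1 10; proposed/C2/C3/EEGNet 20;
ShallowConvNet 50 — fixed convergence points, not re-derived per run).
Probability ties at 0.5 predict HC. Metrics: accuracy, sensitivity
(MDD = positive), specificity. Per-epoch test-accuracy curves can be
recorded for overfitting reports but play no role in model selection.

A two-sided exact binomial band (`chance_band`) gives the accuracy range
consistent with label-independent guessing. Note that LOSO accuracy on
truly null data is *overdispersed* relative to the binomial because fold
outcomes share almost all training data; in particular deterministic
pipelines can anti-learn (systematically below chance) on null cohorts.
The recovery experiments therefore read the band one-sidedly — no
variant may *exceed* the upper edge on null data — and treat below-band
excursions as the no-skill phenomenon they are.

## Synthetic cohort generator

Each subject is a task paradigm (default: 30-s initial rest, then three
30-s task blocks separated by 30-s rests) with:

* **Activation**: boxcar convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, ratio 1/6), peak-normalized; per-channel
  peak amplitude `amp_class · s · g_pair`, where `s` (per subject,
  1 + 0.1·N(0,1) by default) and `g_pair` (per mirror pair, shared
  between partners) model between-subject and spatial variability.
* **Asymmetry**: the right-hemisphere member of each pair is scaled by
  `1 − a·u`, `u ~ Uniform(0.5, 1)` drawn once per subject; `a` is the
  class asymmetry index (direction configurable — the literature is
  mixed on lateralization direction in depression).
* **ΔHbR**: −⅓ of the ΔHbO activation delayed 1 s, plus its own scaled
  noise draw — typical empirical HbR/HbO coupling.
* **Noise**: Mayer wave (0.1 Hz) and respiratory (0.25 Hz) sinusoids
  with random phases, linear drift, white sensor noise. Systemic
  components are *pair-coherent*: mirror partners share phases and drift
  slopes, as systemic physiology on a symmetric montage does, while
  white noise is independent per channel. Default amplitudes are
  10–30% of the control activation amplitude.
* **OD projection**: optionally the concentrations are projected to
  dual-wavelength OD through the same Beer–Lambert forward model the
  preprocessing inverts.

Subject `k` of a cohort uses `SeedSequence((cohort_seed, k))`; cohorts
are pure functions of their configuration.

**What the generator does not emulate:** photon transport and scattering
(the OD projection is the idealized linear model), motion artifacts,
short-separation channels, heartbeat (above the band-pass), non-HRF
response shapes, or any claim about clinical effect sizes. Passing
recovery experiments demonstrates that the pipeline detects the injected
structure — not that it attains any particular accuracy on clinical
data.

## Recovery experiment conditions

Three named study conditions drive the synthetic benchmarks (effect
sizes calibrated once so each condition plays its designed role; they
are properties of the benchmark, not clinical estimates):

* **high-contrast** — strong MDD hypoactivation (amplitude 0.3 vs 1.0)
  plus asymmetry 0.6, noise at half default: a competent pipeline must
  beat the chance band here.
* **null** — identical generating parameters for both classes: no
  variant may exceed the chance band's upper edge.
* **asymmetry-only** — equal class amplitudes; the classes differ only
  through the asymmetry index (0.6), under strong pair-coherent systemic
  noise (Mayer 0.5, respiratory 0.4, drift 0.3 µM), between-subject
  amplitude spread 0.3, pair-gain spread 0.2 (shared within a pair) and
  white noise 0.05 µM. Absolute amplitude is then an unreliable cue and
  the left/right structure within mirror pairs carries the dominant
  reliable signal — the condition designed to separate the mirror-pair
  channel embedding from the same architecture with a randomized channel
  order (C3). Each replicate draws a fresh cohort, network seed and
  shuffle.

Problem sizes used in the shipped experiments: 40 subjects for
high-contrast, 24 for null, 24 per replicate × 10 replicates for
asymmetry-only.

A caveat the replicate experiment makes explicit: the depthwise temporal
layer gives every channel an independent kernel, so at initialization the
two members of a mirror pair are filtered *differently* and pair-coherent
nuisance does not cancel in the spatial pair features. The pairing
advantage therefore has to be trained into the temporal kernels, and at
the fixed recipe (learning rate 0.001, 20 epochs, batch 32) a
two-dozen-subject fold supplies only ~20–40 optimizer steps — enough for
the dense block to exploit whatever separation the quasi-frozen branches
offer, but not to align pair kernels. Measured consequence: the proposed
model scores at or above C3 in most replicates and its mean margin is
positive, but strict per-replicate wins land around 6–7 of 10 (a
leave-one-subject-out ceiling analysis with an oracle linear readout of
the frozen features gives ~7 of 10, ties included). The replicate test
asserts the stronger ≥ 8/10 ordering and currently fails by design
honesty rather than being weakened; realizing the full trained-pairing
advantage would require cohorts or training schedules well beyond the
fixed recipe at desk scale.

## Handcrafted-feature baselines

Six statistics per indicator-channel trace — mean, variance, kurtosis
(Pearson, non-excess), skewness (adjusted Fisher–Pearson), peak value
(signed maximum), time-to-peak (argmax latency in seconds, first-index
tie-break) — give 2,448 features. Per LOSO fold: z-scoring with
training-fold mean and population SD (zero-variance features map to 0
with a warning), Fisher score
`F = Σ_c n_c(μ_c − μ)² / Σ_c n_c σ_c²` (ties broken by feature index),
then for each N = 1..50 a classifier on the top-N features; the maximum
per-N accuracy is the designated accuracy. Classifiers: LDA with lsqr
solver and Ledoit–Wolf analytic shrinkage; linear SVM with L2 penalty,
C = 1. All of these conventions are open in the source toolboxes and
therefore explicit keyword choices here.

## Numerical conventions and degenerate inputs

* Filters reject cutoffs at/above Nyquist and inverted bands.
* MBLL refuses singular extinction systems (determinant < 1e−18).
* k at the (0, 0) vector is 0; log activation clips at 1e−6.
* Constant traces: variance 0, time-to-peak 0, skew/kurtosis mapped from
  NaN to 0.
* Softmax probabilities are clipped at 1e−12 inside the loss only.
* Max-norm constraints rescale kernel columns (per output unit) after
  each optimizer step.

## Known limitations

* The numpy network core is CPU-only and unbatched across folds; LOSO
  at hundreds of subjects is minutes, not seconds.
* The montage is a geometric idealization; with a vendor layout the
  pairing is only as good as the supplied coordinates.
* With ~20–40 optimizer steps per fold (small cohorts at the fixed
  recipe), convolutional weights stay near initialization and class
  information is read out mainly by the dense block from
  quasi-random projections; architectural differences therefore appear
  as feature-SNR differences, which is precisely what the
  asymmetry-only condition isolates.
* The band-pass keeps the Mayer band (0.1 Hz) by design, so systemic
  oscillations are attenuated only by segment averaging.
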