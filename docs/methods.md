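# Methods

## The problem

Overnight audio recorded by a bedside microphone carries enough information
about breathing and body movement to score sleep stages in 30-second epochs.
A staging model trained on clean, controlled recordings (a sleep laboratory,
one fixed microphone) degrades badly on recordings made at home: household
noise (appliances, fans, traffic) and heterogeneous phone microphones shift
the input distribution, and home nights with ground-truth stage labels are
scarce. `sonosleep` implements a training recipe for exactly this situation:

1. **Supervised learning** (`L_c`, cross-entropy) on a labeled clean
   *source* domain;
2. **Adversarial unsupervised domain adaptation** to an unlabeled noisy
   *target* domain: a domain discriminator is trained to tell domains apart
   from the extracted features while the feature extractor — through a
   gradient-reversal layer — is trained to defeat it (`L_d`, binary
   cross-entropy), plus an auxiliary target-domain loss `L_a` (posterior
   conditional entropy + virtual adversarial training) that preserves
   classification performance while the features move;
3. **Consistency training** (`L_js`): household-noise mel spectrograms are
   mixed into clean source windows at SNRs drawn uniformly from
   [-10, 10] dB, and the Jensen–Shannon divergence among the posteriors of
   the clean window and two such augmentations is minimized.

All three components run concurrently in every optimizer step, as a single
weighted sum `L = w_c L_c + w_d L_d + w_a L_a + w_js L_js`.

## Data representation

Audio is cut into 30-s epochs; each epoch becomes a nonnegative mel-power
matrix (triangular filterbank on the HTK mel scale, Hann-windowed rFFT
power). The network consumes **windows of 40 consecutive epochs and emits
stage posteriors for the middle 20** (W, N1, N2, N3, REM), so every
prediction sees ±10 epochs (5 min) of context. At inference the night is
reflect-padded by 10 epochs on each side and tiled at stride 20, so every
true epoch falls in exactly one window's middle slice (a ragged tail is
covered by shifting the last window back; later windows win on overlap).
Posterior argmax ties resolve to the lowest stage index in
(W, N1, N2, N3, REM) order.

Inputs are standardized as log10 power, z-scored per mel bin. The default
("window") mode takes the statistics from each window itself, which cancels
static channel coloration and gain differences between recording setups —
without it, the target domain's microphone filter and noise floor push
inputs several standard deviations off the source distribution and every
model variant collapses to the majority class. A "dataset" mode using
stored source-domain statistics is available as configuration. Adversarial
and virtual-adversarial perturbations live in these z-score units.

## Network

The architecture is deliberately configurable and desk-scale; nothing about
it is a fidelity claim:

* per-epoch encoder: one 3x3 valid convolution (4 channels) -> ReLU ->
  2x2 average pooling -> linear embedding (16 dims) -> ReLU;
* temporal context: one single-head self-attention block over the 40-epoch
  sequence with a residual connection and output projection;
* classifier: per-epoch linear layer + softmax over the middle 20 epochs;
* domain discriminator: temporal convolution (kernel 3) over the
  post-context features -> ReLU -> mean pooling -> two fully connected
  layers -> sigmoid. It consumes the same features the classifier sees,
  through a gradient-reversal layer during training.

The whole model runs on an in-repo reverse-mode autograd over numpy arrays
(float32 on the network path; float64 in the loss oracles). Forward passes
in evaluation mode are pure functions of (parameters, input).

## Losses and numerics

Natural logarithms throughout; probabilities are clamped at 1e-7 before any
log. Conditional entropy is bounded by ln 5, the three-way Jensen–Shannon
divergence by ln 3. VAT finds its perturbation by xi-scaled power iteration
(xi = 1e-6, one iteration) and measures KL(p(x) || p(x + r_adv)) with the
clean posterior held constant; parameters receive no gradient during the
power iteration. The radius epsilon is an L2 norm over the whole window
input (default 1.0); because that input has ~37k dimensions, the benchmark
configuration uses epsilon = 8 (~0.04 sigma per bin) so that the smoothness
penalty actually binds — at epsilon = 1 the per-bin perturbation is ~0.005
sigma and the term is inert. Note that VAT is a
second-order method: against a brute-force direction search its loss agrees
only in the small-epsilon regime (at epsilon ~ 0.5 the true maximizer tilts
away from the curvature direction by tens of percent — a property of the
method, not a defect).

Mel-space noise mixing imitates coherent waveform addition: per
time-frequency bin the mixed power is `c + n + 2 sqrt(c n) cos(phi)` with an
independent phase difference phi ~ Uniform[0, 2pi), floored at zero; the
noise matrix is pre-scaled so whole-epoch clean/noise total power matches
the requested SNR. Whether to floor or renormalize after the cross term is
an interpretation; flooring was chosen. All-zero clean input is rejected
(SNR undefined); all-zero noise clips are rejected.

Default loss weights are (w_c, w_d, w_a, w_js) = (1, 1, 0.1, 1) — a small
auxiliary weight, as is conventional when combining VAT and conditional
entropy with adversarial alignment; none of these is dictated by the
problem and all are configuration. The ablation variants force the weights
of disabled components to exactly zero and skip their computation, so
disabled components contribute no gradient at all.

## Training schedule

The stock `TrainConfig` follows the original recipe: Adam, fixed learning
rate 2e-4, 20 epochs, all components concurrent from step one. That recipe
presumes a well-initialized (pretrained) network. No pretrained weights
exist for this implementation, so `default_benchmark_train_config()` — used
for the synthetic benchmark — substitutes self-pretraining: learning rate
1e-3, and the first 8 of the 20 epochs run the supervised component only,
after which the enabled components join. Without the warmup the conditional
entropy and consistency terms are minimized by the degenerate
"same stage everywhere" solution before the classifier has found the real
one, and training locks in a majority-class predictor. The
gradient-reversal coefficient ramps up over the first 30% of post-warmup
steps and is capped at 0.3: with instance-normalized inputs the features
carry little domain information, the discriminator hovers near chance, and
stronger reversal only feeds gradient noise into the feature extractor.
Batch size is 8 windows per domain per step (small batches give the
20-epoch budget enough optimizer steps to fit the source domain reliably).

## The synthetic benchmark

The three private clinical datasets are emulated by a generator whose
defaults define the study conditions of this package:

* **Hypnograms**: first-order Markov chains over (W, N1, N2, N3, REM) with
  strong self-transitions (~0.75-0.9) and rare W<->REM transitions; nights
  start awake. The matrix is plausible sleep continuity, not a cohort fit.
* **Breathing audio** (2 kHz synthesis rate): band-limited noise
  (stage-dependent center, ~350-450 Hz) amplitude-modulated by Gaussian
  bumps at the subject's breathing rate. Stage structure: N3 slow, loud and
  regular (interval CV ~0.03), REM irregular (CV ~0.35), N1/N2 intermediate,
  W quiet breathing plus broadband movement bursts (~2.5 per epoch).
  Subjects vary in base rate (11-18 /min), loudness, apnea event rate
  (0-20 /h; an event silences breathing for 10-20 s), and movement level.
* **Domain shift**: target-domain audio passes a fixed low-shelf "phone
  microphone" filter, gets a per-night gain jitter (0.7-1.3), and receives
  two synthetic household-noise tracks (hum / fan / transient / colored)
  mixed at a per-night SNR drawn from [0, 10] dB. The noise bank for
  consistency training contains independent draws from the same generator
  families, mel-converted with the dataset configuration.
* **Scale**: 12 source nights, 12 target nights, 6 labeled target test
  nights of 240 epochs (2 h) each; 32 mel bins, 20-1000 Hz, 1.024-s frames
  at 1.0-s hop (29 frames per epoch); 24 noise clips. Subject identities are
  disjoint across splits by construction. These sizes were chosen so the
  full 4-variant x 3-seed ablation runs on a single CPU in minutes while
  every training component still has a measurable effect.

The benchmark is learnable by construction — a rule-based classifier on the
generator's own waveform features (high-band energy for movement bursts,
breathing-interval CV for REM) reaches >80% 3-stage accuracy on clean
source epochs — and the domain gap is real at the input level: a linear
classifier on per-bin log-mel window summaries separates the domains
essentially perfectly before any feature learning
(`trainer.input_domain_separability`). After per-window normalization and
stage-only training, the *feature-level* gap is much smaller (a fresh
discriminator head on frozen supervised features reads ~0.5-0.6): the
extractor discards most domain cues on its own, which is why on this
benchmark adversarial transfer learning alone adds little while
consistency training and the full combination add the most. The expected
ablation shape is full > +CT > +TL ~ supervised.

What the generator does **not** emulate: real respiratory acoustics
(snoring spectra, OSA event structure), inter-night subject identity,
nonstationary home noise with diurnal structure, room reverberation, or
microphone clipping. Passing the benchmark shows the training machinery
works end to end and in the right direction; it does not certify clinical
accuracy.

One deliberate benchmark choice: adaptive noise reduction is **off** in the
benchmark preprocessing chain. The synthetic noises are exactly stationary,
so spectral subtraction removes them almost completely and would erase the
very domain gap the benchmark exists to create; real household noise is not
so obliging. The denoiser (magnitude spectral subtraction against a rolling
20th-percentile per-bin floor, over-subtraction 2.0, spectral floor 0.05)
remains in the API for real recordings and is tested on constructed
signals: it removes >90% of stationary white-noise power while keeping a
transient chirp within 3 dB.

## Evaluation

Agreement is scored after collapsing the 5 stages into 5/4/3/2-class
schemes (4: N1+N2=Light, N3=Deep; 3: N1+N2+N3=NREM; 2: all non-wake=Sleep).
From the pooled confusion matrix: accuracy, Cohen kappa
(p_o - p_e)/(1 - p_e), macro F1 (a zero-support class contributes F1 = 0;
kappa is reported as absent when p_e = 1), and mean per-class sensitivity
(unweighted mean recall over classes present in the reference). Kappa is
pooled across epochs rather than averaged per night.

Per-night sleep metrics follow the standard clinical definitions: TST = 30 s
x sleep epochs; SOL = lights-off to first sleep epoch (lights-off defaults
to recording start for audio-only nights); SE = TST / recording time; WASO
= wake between first and last sleep epochs; REM latency = first sleep epoch
to first REM epoch; stage portions = stage time / recording time. SOL, WASO
and REM latency are reported as absent when undefined. Bland–Altman
agreement uses test-minus-reference differences, limits of agreement at
mean ± 1.96 SD (n-1 denominator), and a t-based 95% CI of the mean
difference. Feature-space structure is visualized by PCA (scikit-learn) on
time-averaged window features.

## Known limitations

* Single-head attention and a one-layer conv encoder saturate well below
  clinical accuracy; the architecture is a config point, sized for CPUs.
* Adversarial adaptation on ~100 windows per domain is noisy across seeds;
  the ablation criteria are therefore stated on seed means, and the
  post-adaptation discriminator accuracy is averaged over the last three
  epochs because the adversarial equilibrium oscillates.
* The phase-randomized mel mixing reproduces the *statistics* of coherent
  addition, not any specific waveform realization.
* Pitch-shift augmentation (resample + phase-vocoder stretch, default ±2
  semitones) operates on waveforms and is exercised in preprocessing tests;
  the training loop operates in mel space and does not use it by default.
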