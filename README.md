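# sonosleep

Sound-based sleep staging for noisy home recordings: supervised
sequence-to-sequence staging on mel-spectrogram windows, adversarial
unsupervised domain adaptation from a clean "hospital" domain to a noisy
"home" domain, and Jensen–Shannon consistency training on noise-augmented
spectrograms — exercised end to end on a bundled synthetic sleep-sound
benchmark.

## The problem

Polysomnography, the gold standard for sleep staging, is expensive and
confined to the laboratory. Breathing and movement sounds recorded by a
bedside microphone are a contact-free alternative, but a model trained on
clean in-lab audio collapses on home recordings: household noise and
heterogeneous phone microphones shift the input distribution, and labeled
home nights are scarce. `sonosleep` trains a staging network with three
concurrent components so that it survives the move:

* **L_c** — supervised cross-entropy on labeled clean-domain windows.
  The network maps 40 consecutive 30-s mel-spectrogram epochs to stage
  posteriors (W, N1, N2, N3, REM) for the middle 20 epochs.
* **L_d** — binary cross-entropy of a domain discriminator, made
  adversarial with a gradient-reversal layer: the discriminator learns to
  tell hospital from home features while the feature extractor learns to
  hide the difference, plus **L_a**, an auxiliary target-domain loss
  (posterior conditional entropy + virtual adversarial training).
* **L_js** — the Jensen–Shannon divergence among the posteriors of a clean
  window and two noise-augmented copies, built by mixing household-noise
  mel spectrograms into clean windows at SNRs drawn from [-10, 10] dB with
  randomized per-bin phase.

The total loss is `w_c L_c + w_d L_d + w_a L_a + w_js L_js`; an ablation
harness trains the four canonical variants (supervised only, +transfer
learning, +consistency training, full).

Because the clinical datasets this methodology was developed on are
private, the package ships a first-class synthetic benchmark
(`sonosleep.simdata`): Markov-chain hypnograms, stage-dependent breathing
audio (rate, regularity, loudness, movement bursts, apnea pauses), a clean
labeled source domain, an unlabeled target domain with a channel filter,
gain jitter and injected household noise, a labeled target test set, and a
synthetic noise bank. See `docs/methods.md` for the model, the generator,
and every numerical choice.

## Worked example

```sh
sonosleep simulate --seed 1 --out bench/
sonosleep train --data bench/ --seed 1 --out run/
sonosleep predict --checkpoint run/checkpoint.npz \
    --mels bench/test_nights/H000_mel.npz --out pred.csv
sonosleep evaluate --pred pred.csv \
    --truth bench/test_nights/H000_hypnogram.csv --scheme 3 --out eval/
```

The same flow through the Python API, on the desk-scale benchmark with the
training configuration tuned for it:

```python
from sonosleep.simdata import GenConfig, build_benchmark
from sonosleep.trainer import (default_benchmark_train_config, fit,
                               evaluate_windows)

bench = build_benchmark(GenConfig(), 42)
model, history = fit(bench.source_train, bench.target_train,
                     default_benchmark_train_config(), bank=bench.bank)
print(evaluate_windows(model, bench.target_test, "three"))
```

which prints (3-stage scheme: wake / NREM / REM, 840 held-out target
epochs):

```
{'accuracy': 0.763095238095238, 'cohen_kappa': 0.5702253257504859,
 'macro_f1': 0.6156255230798381, 'mean_per_class_sensitivity': 0.6097605760467726}
```

Accuracy is the fraction of epochs staged correctly; Cohen kappa corrects
that for chance agreement under the marginals; macro F1 and mean per-class
sensitivity weight the three classes equally, so they drop when a rare
class (here REM) is missed. `sonosleep evaluate` additionally writes
per-night clinical sleep metrics (TST, SOL, SE, WASO, REM latency, stage
portions) and a Bland–Altman agreement summary across nights.

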