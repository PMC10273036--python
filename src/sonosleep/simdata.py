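"""Synthetic sleep-sound benchmark.

Emulates the three-way data situation of home sleep staging from audio: a
labeled clean "hospital" source domain, an unlabeled noisy "home" target
domain (same physiology, different acoustic channel plus household noise),
and a labeled held-out target test set, together with a bank of home-noise
clips for consistency training.

Ground-truth hypnograms are first-order Markov chains over
(W, N1, N2, N3, REM). Each epoch's audio is amplitude-modulated band-limited
noise imitating breathing sounds, with stage-dependent rate, regularity and
loudness (slow regular deep-sleep breathing, irregular REM breathing, wake
epochs with movement bursts), occasional apnea pauses, and a small
microphone noise floor. Target-domain audio additionally passes a fixed
low-shelf channel filter (a stand-in for smartphone microphones), gets a
per-night gain jitter, and has synthetic household noise (hum, fan,
transients, colored noise) mixed in at a per-night SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import butter, sosfilt, lfilter

from .augment import NoiseBank
from .hypnogram import STAGES, Hypnogram
from .sigproc import (
    EpochWaveform,
    MelConfig,
    MelEpoch,
    NoiseFloorState,
    StageWindow,
    adaptive_noise_reduce,
    mel_spectrogram,
    windowize,
)

NOISE_KINDS = ("hum", "fan", "transient", "colored")


# ---------------------------------------------------------------------------
# hypnogram simulation


def default_transition_matrix() -> np.ndarray:
    """Plausible sleep-continuity chain (high self-transition, rare W<->REM).

    Synthetic; not fitted to any cohort.
    """
    return np.array(
        [
            # W     N1     N2     N3     REM
            [0.90, 0.070, 0.020, 0.005, 0.005],  # W
            [0.08, 0.750, 0.150, 0.005, 0.015],  # N1
            [0.02, 0.040, 0.880, 0.040, 0.020],  # N2
            [0.01, 0.005, 0.065, 0.900, 0.020],  # N3
            [0.03, 0.030, 0.040, 0.000, 0.900],  # REM
        ]
    )


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Left eigenvector of the chain for eigenvalue 1, normalized to sum 1."""
    vals, vecs = np.linalg.eig(transition_matrix.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(
    rng: np.random.Generator,
    n_epochs: int,
    transition_matrix: Optional[np.ndarray] = None,
    initial_dist: Optional[np.ndarray] = None,
) -> Hypnogram:
    """First-order Markov sample of stage labels for one night."""
    P = default_transition_matrix() if transition_matrix is None else \
        np.asarray(transition_matrix, dtype=np.float64)
    if P.shape != (5, 5) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0,
                                                            atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic 5x5")
    if initial_dist is None:
        init = np.array([1.0, 0.0, 0.0, 0.0, 0.0])  # nights start awake
    else:
        init = np.asarray(initial_dist, dtype=np.float64)
        if not np.isclose(init.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(5, p=init)
    for i in range(1, n_epochs):
        states[i] = rng.choice(5, p=P[states[i - 1]])
    return Hypnogram.from_indices(states)


# ---------------------------------------------------------------------------
# subject physiology


@dataclass
class StageSoundParams:
    rate_mult: float      # multiplier on the subject's base breathing rate
    jitter: float         # CV of breath-to-breath intervals
    amp_mult: float       # loudness multiplier
    burst_rate: float     # expected movement bursts per 30-s epoch
    center_hz: float      # breathing-sound band center


DEFAULT_STAGE_SOUNDS: dict[str, StageSoundParams] = {
    "W": StageSoundParams(1.15, 0.25, 0.60, 2.50, 450.0),
    "N1": StageSoundParams(1.08, 0.15, 0.85, 0.30, 420.0),
    "N2": StageSoundParams(1.00, 0.08, 1.00, 0.05, 400.0),
    "N3": StageSoundParams(0.85, 0.03, 1.30, 0.00, 350.0),
    "REM": StageSoundParams(1.10, 0.35, 0.90, 0.10, 430.0),
}


@dataclass
class SubjectProfile:
    """Per-subject acoustics: base breathing rate, loudness, event rates."""

    breathing_rate: float = 14.0        # breaths/min, 8-25 enforced
    amplitude: float = 0.10
    apnea_rate: float = 5.0             # events/hour
    movement_scale: float = 1.0         # scales stage burst rates
    stage_sounds: dict[str, StageSoundParams] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_SOUNDS)
    )

    def __post_init__(self):
        if not 8.0 <= self.breathing_rate <= 25.0:
            raise ValueError("breathing rate outside physiologic 8-25 /min")


def sample_profile(rng: np.random.Generator) -> SubjectProfile:
    return SubjectProfile(
        breathing_rate=float(rng.uniform(11.0, 18.0)),
        amplitude=float(rng.uniform(0.08, 0.15)),
        apnea_rate=float(rng.uniform(0.0, 20.0)),
        movement_scale=float(rng.uniform(0.7, 1.3)),
    )


def sample_breath_intervals(
    stage: str,
    profile: SubjectProfile,
    rng: np.random.Generator,
    duration: float = 30.0,
) -> np.ndarray:
    """Breath-to-breath intervals (s) filling one epoch for the given stage."""
    sp = profile.stage_sounds[stage]
    mean = 60.0 / (profile.breathing_rate * sp.rate_mult)
    intervals = []
    total = 0.0
    while total < duration + mean:
        iv = rng.normal(mean, sp.jitter * mean)
        iv = float(np.clip(iv, 0.4 * mean, 2.2 * mean))
        intervals.append(iv)
        total += iv
    return np.asarray(intervals)


_SOS_CACHE: dict = {}


def _bandpass(sr: int, lo: float, hi: float):
    key = (sr, round(lo, 1), round(hi, 1))
    if key not in _SOS_CACHE:
        _SOS_CACHE[key] = butter(2, [lo, hi], btype="band", fs=sr, output="sos")
    return _SOS_CACHE[key]


def _lowpass(sr: int, fc: float, order: int = 2):
    key = (sr, "lp", round(fc, 1), order)
    if key not in _SOS_CACHE:
        _SOS_CACHE[key] = butter(order, fc, btype="low", fs=sr, output="sos")
    return _SOS_CACHE[key]


def channel_filter(x: np.ndarray, sr: int) -> np.ndarray:
    """Fixed low-shelf 'smartphone microphone' coloration for the target domain."""
    return 0.75 * x + 1.6 * sosfilt(_lowpass(sr, 200.0), x)


def synth_epoch(
    stage: str,
    profile: SubjectProfile,
    domain: str,
    rng: np.random.Generator,
    sample_rate: int = 2000,
    return_events: bool = False,
):
    """One 30-s epoch of breathing sound for the given stage.

    Breathing is band-limited noise amplitude-modulated by Gaussian bumps at
    stage-dependent rate/regularity; wake epochs add broadband movement
    bursts; apnea pauses are inserted at the profile's event rate. Target
    domain audio passes the fixed channel filter.
    """
    sp = profile.stage_sounds[stage]
    n = int(round(30.0 * sample_rate))
    t_axis = np.arange(n) / sample_rate

    intervals = sample_breath_intervals(stage, profile, rng)
    times = np.cumsum(intervals) - intervals[0] + rng.uniform(0.0, intervals[0])
    times = times[times < 30.0]

    # apnea: silence breathing for 10-20 s with per-epoch probability
    apnea = rng.random() < profile.apnea_rate / 120.0
    if apnea and len(times) > 0:
        start = rng.uniform(0.0, 20.0)
        times = times[(times < start) | (times > start + rng.uniform(10.0, 20.0))]

    envelope = np.zeros(n)
    mean_iv = float(np.mean(intervals))
    for tb in times:
        width = 0.18 * mean_iv
        amp = 1.0 + 0.15 * rng.standard_normal()
        lo = max(0, int((tb - 4 * width) * sample_rate))
        hi = min(n, int((tb + 4 * width) * sample_rate))
        envelope[lo:hi] += amp * np.exp(
            -0.5 * ((t_axis[lo:hi] - tb) / width) ** 2
        )

    carrier = sosfilt(
        _bandpass(sample_rate, sp.center_hz - 150.0, sp.center_hz + 150.0),
        rng.standard_normal(n),
    )
    amp0 = profile.amplitude * sp.amp_mult
    x = amp0 * envelope * carrier

    n_bursts = rng.poisson(sp.burst_rate * profile.movement_scale)
    for _ in range(n_bursts):
        dur = rng.uniform(0.3, 1.0)
        start = rng.uniform(0.0, 30.0 - dur)
        i0, i1 = int(start * sample_rate), int((start + dur) * sample_rate)
        decay = np.exp(-np.arange(i1 - i0) / (0.25 * dur * sample_rate))
        x[i0:i1] += 8.0 * amp0 * decay * rng.standard_normal(i1 - i0)

    x += 0.003 * rng.standard_normal(n)  # microphone floor
    if domain == "target":
        x = channel_filter(x, sample_rate)

    epoch = EpochWaveform(x, sample_rate)
    if return_events:
        return epoch, {"breath_times": times, "n_bursts": int(n_bursts),
                       "apnea": bool(apnea)}
    return epoch


# ---------------------------------------------------------------------------
# household noise clips


def synth_noise_clip(
    kind: str,
    rng: np.random.Generator,
    sample_rate: int = 2000,
    seconds: float = 30.0,
) -> EpochWaveform:
    """A 30-s clip of household noise of the named character."""
    n = int(round(seconds * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "hum":
        f0 = rng.uniform(50.0, 120.0)
        x = np.zeros(n)
        for h in range(1, 6):
            x += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
        x = 0.05 * x / np.std(x) + 0.002 * rng.standard_normal(n)
    elif kind == "fan":
        x = sosfilt(_lowpass(sample_rate, 300.0, order=4), rng.standard_normal(n))
        wobble = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.2, 1.0) * t
                                    + rng.uniform(0, 2 * np.pi))
        x = 0.05 * wobble * x / np.std(x)
    elif kind == "transient":
        x = 0.002 * rng.standard_normal(n)
        for _ in range(max(3, rng.poisson(8.0))):
            dur = rng.uniform(0.02, 0.10)
            start = rng.uniform(0.0, seconds - dur)
            i0, i1 = int(start * sample_rate), int((start + dur) * sample_rate)
            decay = np.exp(-np.arange(i1 - i0) / (0.2 * dur * sample_rate))
            x[i0:i1] += rng.uniform(0.15, 0.4) * decay * rng.standard_normal(i1 - i0)
    elif kind == "colored":
        x = lfilter([1.0], [1.0, -0.98], rng.standard_normal(n))
        x = 0.05 * x / np.std(x)
    else:
        raise ValueError(f"unknown noise kind {kind!r}; expected one of {NOISE_KINDS}")
    return EpochWaveform(x, sample_rate)


def build_noise_bank(
    rng: np.random.Generator,
    mel_config: MelConfig,
    n_clips: int = 24,
    sample_rate: int = 2000,
) -> NoiseBank:
    clips, kinds, ids = [], [], []
    for i in range(n_clips):
        kind = NOISE_KINDS[i % len(NOISE_KINDS)]
        clip = synth_noise_clip(kind, rng, sample_rate)
        clips.append(mel_spectrogram(clip, mel_config).values)
        kinds.append(kind)
        ids.append(f"{kind}{i:03d}")
    return NoiseBank(np.stack(clips), tuple(kinds), tuple(ids))


# ---------------------------------------------------------------------------
# benchmark assembly


@dataclass
class GenConfig:
    """Desk-scale benchmark: sizes chosen so the full ablation runs on one CPU."""

    n_source_nights: int = 12
    n_target_nights: int = 12
    n_test_nights: int = 6
    epochs_per_night: int = 160
    sample_rate: int = 2000
    mel: MelConfig = field(
        default_factory=lambda: MelConfig(
            sample_rate=2000, n_mels=32, frame_seconds=1.024,
            hop_seconds=1.0, fmin=20.0, fmax=1000.0,
        )
    )
    stride: int = 20
    noise_bank_clips: int = 24
    target_snr_db: tuple[float, float] = (0.0, 10.0)
    target_gain_jitter: tuple[float, float] = (0.7, 1.3)
    noise_reduce: bool = False


@dataclass
class TestNight:
    night_id: str
    mel: np.ndarray  # [n_epochs x n_mels x n_frames]
    hypnogram: Hypnogram


@dataclass
class SyntheticBenchmark:
    source_train: list[StageWindow]
    target_train: list[StageWindow]
    target_test: list[StageWindow]
    bank: NoiseBank
    test_nights: list[TestNight]
    gen_config: GenConfig
    seed: int


def _synth_night(
    night_rng: np.random.Generator,
    cfg: GenConfig,
    domain: str,
) -> tuple[np.ndarray, Hypnogram]:
    """Mel epochs [N x M x F] + hypnogram for one night of one subject."""
    profile = sample_profile(night_rng)
    hyp = simulate_hypnogram(night_rng, cfg.epochs_per_night)
    epochs = [
        synth_epoch(stage, profile, domain, night_rng, cfg.sample_rate)
        for stage in hyp.stages
    ]
    if domain == "target":
        # household noise at a per-night SNR vs the night's median epoch power
        kinds = night_rng.choice(len(NOISE_KINDS), size=2, replace=False)
        track = (
            synth_noise_clip(NOISE_KINDS[kinds[0]], night_rng, cfg.sample_rate).samples
            + synth_noise_clip(NOISE_KINDS[kinds[1]], night_rng,
                               cfg.sample_rate).samples
        )
        track = channel_filter(track, cfg.sample_rate)
        snr_db = night_rng.uniform(*cfg.target_snr_db)
        p_clean = np.median([np.mean(e.samples**2) for e in epochs])
        p_noise = np.mean(track**2)
        alpha = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
        gain = night_rng.uniform(*cfg.target_gain_jitter)
        for e in epochs:
            offset = int(night_rng.integers(0, len(track)))
            e.samples = gain * (e.samples + alpha * np.roll(track, -offset))
    if cfg.noise_reduce:
        state = NoiseFloorState()
        epochs = [adaptive_noise_reduce(e, state) for e in epochs]
    mel = np.stack([mel_spectrogram(e, cfg.mel).values for e in epochs])
    return mel, hyp


def build_benchmark(
    gen_config: Optional[GenConfig] = None,
    rng: np.random.Generator | int | None = None,
) -> SyntheticBenchmark:
    """Generate the full three-split benchmark plus noise bank.

    Subject identities are disjoint across splits by construction (S*/T*/H*
    prefixes); labels are attached only to source_train and target_test
    windows. Deterministic given the seed.
    """
    cfg = gen_config or GenConfig()
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    root = np.random.SeedSequence(rng.integers(0, 2**31 - 1))
    streams = root.spawn(
        cfg.n_source_nights + cfg.n_target_nights + cfg.n_test_nights + 1
    )

    source_train: list[StageWindow] = []
    target_train: list[StageWindow] = []
    target_test: list[StageWindow] = []
    test_nights: list[TestNight] = []
    subject_ids: set[str] = set()
    k = 0

    for i in range(cfg.n_source_nights):
        night_rng = np.random.default_rng(streams[k]); k += 1
        mel, hyp = _synth_night(night_rng, cfg, "source")
        source_train.extend(
            windowize(mel, labels=hyp.stages, stride=cfg.stride, domain="source")
        )
        subject_ids.add(f"S{i:03d}")

    for i in range(cfg.n_target_nights):
        night_rng = np.random.default_rng(streams[k]); k += 1
        mel, _ = _synth_night(night_rng, cfg, "target")
        target_train.extend(windowize(mel, stride=cfg.stride, domain="target"))
        subject_ids.add(f"T{i:03d}")

    for i in range(cfg.n_test_nights):
        night_rng = np.random.default_rng(streams[k]); k += 1
        mel, hyp = _synth_night(night_rng, cfg, "target")
        target_test.extend(
            windowize(mel, labels=hyp.stages, stride=cfg.stride, domain="target")
        )
        test_nights.append(TestNight(f"H{i:03d}", mel, hyp))
        subject_ids.add(f"H{i:03d}")

    expected = cfg.n_source_nights + cfg.n_target_nights + cfg.n_test_nights
    assert len(subject_ids) == expected, "subject ids must be disjoint across splits"

    bank_rng = np.random.default_rng(streams[k])
    bank = build_noise_bank(bank_rng, cfg.mel, cfg.noise_bank_clips, cfg.sample_rate)
    return SyntheticBenchmark(
        source_train, target_train, target_test, bank, test_nights, cfg, seed
    )


# ---------------------------------------------------------------------------
# persistence


def _save_windows(path, windows: list[StageWindow]) -> None:
    arrays = {
        "mel": np.stack([w.mel for w in windows]),
        "starts": np.array([w.start_epoch for w in windows]),
        "domain": np.bytes_(windows[0].domain),
    }
    if windows[0].labels is not None:
        arrays["labels"] = np.stack(
            [np.asarray(w.labels, dtype="<U4") for w in windows]
        )
    np.savez_compressed(path, **arrays)


def load_windows(path) -> list[StageWindow]:
    with np.load(path) as z:
        mel = z["mel"]
        starts = z["starts"]
        domain = bytes(z["domain"]).decode()
        labels = z["labels"] if "labels" in z else None
    out = []
    for i in range(len(mel)):
        lab = None if labels is None else labels[i].astype(object)
        out.append(StageWindow(mel[i], lab, domain, int(starts[i])))
    return out


def save_benchmark(bench: SyntheticBenchmark, outdir) -> None:
    """Write all splits, the noise bank, and per-night test data to a directory."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from .hypnogram import write_hypnogram_csv
    from .sigproc import save_mel_archive

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _save_windows(outdir / "source_train.npz", bench.source_train)
    _save_windows(outdir / "target_train.npz", bench.target_train)
    _save_windows(outdir / "target_test.npz", bench.target_test)
    np.savez_compressed(
        outdir / "noise_bank.npz",
        clips=bench.bank.clips,
        kinds=np.array(bench.bank.kinds, dtype="<U16"),
        clip_ids=np.array(bench.bank.clip_ids, dtype="<U24"),
    )
    nights_dir = outdir / "test_nights"
    nights_dir.mkdir(exist_ok=True)
    for night in bench.test_nights:
        save_mel_archive(
            nights_dir / f"{night.night_id}_mel.npz", night.mel, bench.gen_config.mel
        )
        write_hypnogram_csv(
            nights_dir / f"{night.night_id}_hypnogram.csv", night.hypnogram
        )
    manifest = asdict(bench.gen_config)
    manifest["seed"] = bench.seed
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_benchmark(indir) -> SyntheticBenchmark:
    import json
    from pathlib import Path

    from .hypnogram import read_hypnogram_csv
    from .sigproc import load_mel_archive

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    seed = manifest.pop("seed")
    mel_cfg = MelConfig(**manifest.pop("mel"))
    manifest["target_snr_db"] = tuple(manifest["target_snr_db"])
    manifest["target_gain_jitter"] = tuple(manifest["target_gain_jitter"])
    cfg = GenConfig(mel=mel_cfg, **manifest)
    with np.load(indir / "noise_bank.npz") as z:
        bank = NoiseBank(z["clips"], tuple(z["kinds"]), tuple(z["clip_ids"]))
    nights = []
    for mel_path in sorted((indir / "test_nights").glob("*_mel.npz")):
        night_id = mel_path.name[: -len("_mel.npz")]
        mel, _ = load_mel_archive(mel_path)
        hyp = read_hypnogram_csv(indir / "test_nights" / f"{night_id}_hypnogram.csv")
        nights.append(TestNight(night_id, mel, hyp))
    return SyntheticBenchmark(
        load_windows(indir / "source_train.npz"),
        load_windows(indir / "target_train.npz"),
        load_windows(indir / "target_test.npz"),
        bank,
        nights,
        cfg,
        seed,
    )
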