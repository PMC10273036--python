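"""Noise augmentation in mel space for consistency training.

Home-noise mel spectrograms are mixed into clean source-domain spectrograms
at a controlled signal-to-noise ratio. The mix imitates coherent addition of
two waveforms: per time-frequency bin the combined power is
c + n + 2*sqrt(c*n)*cos(phi) with an independent random phase difference
phi ~ Uniform[0, 2pi), floored at zero. A consistency triplet is the clean
window plus two augmentations with distinct noise clips and independent SNR
draws from Uniform[-10, 10] dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sigproc import (
    MelConfig,
    MelEpoch,
    NoiseFloorState,
    StageWindow,
    adaptive_noise_reduce,
    load_wav,
    mel_spectrogram,
    segment_epochs,
)

SNR_RANGE_DB: tuple[float, float] = (-10.0, 10.0)


@dataclass
class NoiseBank:
    """Collection of mel-space noise clips, each [n_mels x n_frames]."""

    clips: np.ndarray  # [n_clips x n_mels x n_frames]
    kinds: tuple[str, ...] = ()
    clip_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.clips.ndim != 3:
            raise ValueError("clips must be stacked [n_clips x n_mels x n_frames]")
        if not self.clip_ids:
            self.clip_ids = tuple(f"clip{i:04d}" for i in range(len(self.clips)))

    def __len__(self) -> int:
        return len(self.clips)


@dataclass
class ConsistencyTriplet:
    clean: StageWindow
    aug1: StageWindow
    aug2: StageWindow
    snr1: float
    snr2: float
    noise_ids: tuple[str, str] = ("", "")


def sample_snr(rng: np.random.Generator,
               snr_range: tuple[float, float] = SNR_RANGE_DB) -> float:
    """Uniform SNR draw in dB over the configured range."""
    return float(rng.uniform(*snr_range))


def fit_clip(noise: np.ndarray, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Tile (with random circular offset) or randomly crop a clip to n_frames."""
    m = noise.shape[1]
    if m == n_frames:
        return noise
    if m < n_frames:
        reps = int(np.ceil(n_frames / m)) + 1
        tiled = np.tile(noise, (1, reps))
        offset = int(rng.integers(0, m))
        return tiled[:, offset : offset + n_frames]
    offset = int(rng.integers(0, m - n_frames + 1))
    return noise[:, offset : offset + n_frames]


def snr_scale(clean_power: float, noise_power: float, snr_db: float) -> float:
    """Factor on noise power so clean/noise total power = 10^(snr/10)."""
    if noise_power <= 0:
        raise ValueError("degenerate noise clip: zero total power")
    if clean_power <= 0:
        raise ValueError("all-zero clean input: SNR undefined")
    return clean_power / (noise_power * 10.0 ** (snr_db / 10.0))


def mix_noise(
    clean: np.ndarray | MelEpoch,
    noise: np.ndarray | MelEpoch,
    snr_db: float,
    rng: np.random.Generator,
) -> np.ndarray | MelEpoch:
    """Mix a noise mel spectrogram into a clean one at the requested SNR.

    Noise power is rescaled so total clean power / total scaled-noise power
    equals 10^(snr_db/10); per-bin combination adds the random-phase cross
    term and floors negatives at zero.
    """
    wrap = isinstance(clean, MelEpoch)
    c = clean.values if wrap else np.asarray(clean, dtype=np.float64)
    n = noise.values if isinstance(noise, MelEpoch) else np.asarray(noise, np.float64)
    if c.shape != n.shape:
        raise ValueError(f"shape mismatch: clean {c.shape} vs noise {n.shape}")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    alpha = snr_scale(float(c.sum()), float(n.sum()), snr_db)
    ns = alpha * n
    phi = rng.uniform(0.0, 2.0 * np.pi, size=c.shape)
    mixed = np.maximum(c + ns + 2.0 * np.sqrt(c * ns) * np.cos(phi), 0.0)
    if wrap:
        return MelEpoch(mixed, clean.epoch_index)
    return mixed


def mix_noise_window(
    window: StageWindow,
    noise_clip: np.ndarray,
    snr_db: float,
    rng: np.random.Generator,
) -> StageWindow:
    """Mix one noise clip into every epoch of a window at a shared SNR.

    Each epoch gets an independently offset copy of the clip and independent
    phases; labels and domain are carried over untouched.
    """
    n_epochs, _, n_frames = window.mel.shape
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    clips = np.stack([fit_clip(noise_clip, n_frames, rng) for _ in range(n_epochs)])
    c = window.mel
    c_pow = c.sum(axis=(1, 2))
    n_pow = clips.sum(axis=(1, 2))
    if np.any(n_pow <= 0):
        raise ValueError("degenerate noise clip: zero total power")
    if np.any(c_pow <= 0):
        raise ValueError("all-zero clean input: SNR undefined")
    alpha = c_pow / (n_pow * 10.0 ** (snr_db / 10.0))
    ns = alpha[:, None, None] * clips
    phi = rng.uniform(0.0, 2.0 * np.pi, size=c.shape)
    mixed = np.maximum(c + ns + 2.0 * np.sqrt(c * ns) * np.cos(phi), 0.0)
    labels = None if window.labels is None else window.labels.copy()
    return StageWindow(mixed, labels, window.domain, window.start_epoch)


def make_triplet(
    clean: StageWindow,
    bank: NoiseBank,
    rng: np.random.Generator,
    snr_range: tuple[float, float] = SNR_RANGE_DB,
) -> ConsistencyTriplet:
    """Clean window + two augmentations with distinct clips and independent SNRs."""
    if len(bank) < 2:
        raise ValueError("insufficient noise bank: need at least 2 clips")
    i, j = rng.choice(len(bank), size=2, replace=False)
    snr1 = sample_snr(rng, snr_range)
    snr2 = sample_snr(rng, snr_range)
    aug1 = mix_noise_window(clean, bank.clips[i], snr1, rng)
    aug2 = mix_noise_window(clean, bank.clips[j], snr2, rng)
    return ConsistencyTriplet(
        clean, aug1, aug2, snr1, snr2, (bank.clip_ids[i], bank.clip_ids[j])
    )


def load_noise_bank_dir(
    directory,
    mel_config: MelConfig,
    manifest: Optional[str] = None,
    noise_reduce: bool = False,
) -> NoiseBank:
    """Build a NoiseBank from a directory of WAV clips.

    With a manifest CSV (`clip_id,filename,kind`) clip identity and kind tags
    come from the manifest; otherwise every *.wav in the directory is used.
    Clips are preprocessed exactly like sleep audio: optional noise reduction
    then mel conversion, one mel clip per 30-s epoch (shorter clips are
    padded by tiling the waveform).
    """
    directory = Path(directory)
    if manifest is not None:
        man = pd.read_csv(manifest)
        entries = [(r.clip_id, directory / r.filename, str(r.kind))
                   for r in man.itertuples()]
    else:
        entries = [(p.stem, p, "unknown") for p in sorted(directory.glob("*.wav"))]
    if not entries:
        raise ValueError(f"no WAV clips found in {directory}")
    clips, kinds, ids = [], [], []
    for clip_id, path, kind in entries:
        samples, rate = load_wav(path)
        n_epoch_src = int(round(30.0 * rate))
        if len(samples) < n_epoch_src:
            reps = int(np.ceil(n_epoch_src / len(samples)))
            samples = np.tile(samples, reps)[:n_epoch_src]
        epochs = segment_epochs(samples, rate)
        if noise_reduce:
            state = NoiseFloorState()
            epochs = [adaptive_noise_reduce(e, state) for e in epochs]
        for e in epochs:
            clips.append(mel_spectrogram(e, mel_config).values)
            kinds.append(kind)
            ids.append(f"{clip_id}_{e.epoch_index}" if len(epochs) > 1 else clip_id)
    return NoiseBank(np.stack(clips), tuple(kinds), tuple(ids))
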