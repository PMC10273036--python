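"""Audio frontend: 30-second epoching, adaptive noise reduction, mel
spectrograms, pitch-shift augmentation, and 40-epoch training windows.

A night of mono audio is cut into 30-second epochs (the sleep-scoring unit),
each epoch is denoised by magnitude spectral subtraction against a rolling
per-bin noise-floor estimate, converted to a mel-scale power spectrogram,
and consecutive epochs are grouped into 40-epoch windows whose middle 20
epochs carry the stage labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly, stft, istft


# ---------------------------------------------------------------------------
# WAV I/O


def load_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV file as float64 in [-1, 1).

    Integer PCM is scaled by its full-scale value; float data passes through.
    Multi-channel files are rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got {data.shape[1]} channels")
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(np.float64) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(np.float64)
    return data, int(rate)


def save_wav(path, samples: np.ndarray, rate: int) -> None:
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, rate, (x * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Epoching


@dataclass
class EpochWaveform:
    """One 30-second chunk of audio: exactly sample_rate * epoch_seconds samples."""

    samples: np.ndarray
    sample_rate: int
    epoch_index: int = 0


def segment_epochs(
    samples: np.ndarray, sample_rate: int, epoch_seconds: float = 30.0
) -> list[EpochWaveform]:
    """Cut audio into non-overlapping epochs, discarding the trailing partial one."""
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    samples = np.asarray(samples, dtype=np.float64)
    n_per = int(round(epoch_seconds * sample_rate))
    n_epochs = len(samples) // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording too short: {len(samples) / sample_rate:.1f} s "
            f"< one {epoch_seconds:.0f}-s epoch"
        )
    return [
        EpochWaveform(samples[i * n_per : (i + 1) * n_per].copy(), sample_rate, i)
        for i in range(n_epochs)
    ]


# ---------------------------------------------------------------------------
# Adaptive noise reduction (magnitude spectral subtraction)


@dataclass
class NoiseReduceConfig:
    frame_seconds: float = 0.032
    percentile: float = 20.0
    buffer_frames: int = 512
    oversubtract: float = 2.0
    spectral_floor: float = 0.05


class NoiseFloorState:
    """Rolling per-frequency-bin magnitude history for the noise-floor estimate.

    The floor is a low percentile of recent STFT magnitudes in each bin, so
    stationary background (hum, fan) is captured while transient respiratory
    events barely move it.
    """

    def __init__(self, config: NoiseReduceConfig | None = None):
        self.config = config or NoiseReduceConfig()
        self._buffer: Optional[np.ndarray] = None  # [n_bins, buffered frames]

    def update(self, magnitudes: np.ndarray) -> None:
        if self._buffer is None:
            self._buffer = magnitudes.copy()
        else:
            self._buffer = np.concatenate([self._buffer, magnitudes], axis=1)
        if self._buffer.shape[1] > self.config.buffer_frames:
            self._buffer = self._buffer[:, -self.config.buffer_frames :]

    def floor(self) -> np.ndarray:
        if self._buffer is None:
            raise RuntimeError("noise-floor state not initialized")
        return np.percentile(self._buffer, self.config.percentile, axis=1)


def adaptive_noise_reduce(
    epoch: EpochWaveform, state: NoiseFloorState
) -> EpochWaveform:
    """Spectral subtraction of the rolling noise floor from one epoch.

    The epoch's own STFT magnitudes are added to the state first (so the very
    first epoch of a recording seeds the estimate), then `oversubtract x floor`
    is removed from each bin magnitude, clipped at `spectral_floor` of the
    original magnitude. Length and sample rate are preserved.
    """
    cfg = state.config
    x = epoch.samples
    nperseg = max(16, int(round(cfg.frame_seconds * epoch.sample_rate)))
    noverlap = nperseg // 2
    _, _, X = stft(x, fs=epoch.sample_rate, nperseg=nperseg, noverlap=noverlap)
    mag, phase = np.abs(X), np.angle(X)
    state.update(mag)
    floor = state.floor()
    cleaned = np.maximum(
        mag - cfg.oversubtract * floor[:, None], cfg.spectral_floor * mag
    )
    _, y = istft(
        cleaned * np.exp(1j * phase),
        fs=epoch.sample_rate,
        nperseg=nperseg,
        noverlap=noverlap,
    )
    if len(y) < len(x):
        y = np.pad(y, (0, len(x) - len(y)))
    return EpochWaveform(y[: len(x)], epoch.sample_rate, epoch.epoch_index)


# ---------------------------------------------------------------------------
# Mel spectrogram


@dataclass
class MelConfig:
    sample_rate: int = 16000
    n_mels: int = 64
    frame_seconds: float = 0.050
    hop_seconds: float = 0.025
    fmin: float = 20.0
    fmax: float = 8000.0

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_seconds * self.sample_rate))

    @property
    def hop_samples(self) -> int:
        return int(round(self.hop_seconds * self.sample_rate))

    @property
    def n_fft(self) -> int:
        return 1 << int(np.ceil(np.log2(self.frame_samples)))

    def n_frames(self, epoch_seconds: float = 30.0) -> int:
        n = int(round(epoch_seconds * self.sample_rate))
        return 1 + (n - self.frame_samples) // self.hop_samples

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "MelConfig":
        return cls(**json.loads(s))


@dataclass
class MelEpoch:
    """Nonnegative mel-power matrix [n_mels x n_frames] for one epoch."""

    values: np.ndarray
    epoch_index: int = 0


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(config: MelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filters on the rFFT grid.

    Returns (filters [n_mels x n_fft//2+1], band edge frequencies in Hz of
    length n_mels + 2).
    """
    edges_hz = mel_to_hz(
        np.linspace(hz_to_mel(config.fmin), hz_to_mel(config.fmax), config.n_mels + 2)
    )
    fft_freqs = np.fft.rfftfreq(config.n_fft, d=1.0 / config.sample_rate)
    filters = np.zeros((config.n_mels, len(fft_freqs)))
    for i in range(config.n_mels):
        lo, ctr, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        filters[i] = np.maximum(0.0, np.minimum(up, down))
    return filters, edges_hz


def mel_spectrogram(epoch: EpochWaveform, config: MelConfig) -> MelEpoch:
    """Mel-scale power spectrogram of one epoch.

    The epoch is resampled to config.sample_rate if needed, framed with a Hann
    window (no padding: n_frames = 1 + floor((N - frame)/hop)), and the rFFT
    power spectrum is pooled through the triangular filterbank. Entries are
    nonnegative and scale quadratically with waveform amplitude.
    """
    x = epoch.samples
    if epoch.sample_rate != config.sample_rate:
        frac = Fraction(config.sample_rate, epoch.sample_rate)
        x = resample_poly(x, frac.numerator, frac.denominator)
    frame, hop = config.frame_samples, config.hop_samples
    if frame > len(x) or hop > len(x):
        raise ValueError("invalid mel config: frame/hop longer than epoch")
    n_frames = 1 + (len(x) - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    window = np.hanning(frame)
    spec = np.abs(np.fft.rfft(x[idx] * window, n=config.n_fft, axis=1)) ** 2
    filters, _ = mel_filterbank(config)
    return MelEpoch((filters @ spec.T), epoch.epoch_index)


# ---------------------------------------------------------------------------
# Pitch shift (resample + phase-vocoder time stretch)


def _phase_vocoder_stretch(x: np.ndarray, n_out: int, nperseg: int = 512) -> np.ndarray:
    """Stretch/compress x to n_out samples at constant pitch."""
    nperseg = min(nperseg, max(32, len(x) // 4))
    hop = nperseg // 4
    _, _, X = stft(x, nperseg=nperseg, noverlap=nperseg - hop)
    n_frames = X.shape[1]
    rate = len(x) / n_out
    steps = np.arange(0, n_frames - 1, rate)
    i0 = steps.astype(int)
    frac = steps - i0
    mag = (1.0 - frac) * np.abs(X[:, i0]) + frac * np.abs(X[:, i0 + 1])
    phi_adv = 2.0 * np.pi * hop * np.arange(X.shape[0]) / nperseg
    dphi = np.angle(X[:, i0 + 1]) - np.angle(X[:, i0]) - phi_adv[:, None]
    dphi = dphi - 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
    phases = np.angle(X[:, [0]]) + np.cumsum(phi_adv[:, None] + dphi, axis=1)
    _, y = istft(
        mag * np.exp(1j * phases), nperseg=nperseg, noverlap=nperseg - hop
    )
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)))
    return y[:n_out]


def pitch_shift(
    epoch: EpochWaveform, semitones: float, rng: np.random.Generator | None = None
) -> EpochWaveform:
    """Shift pitch by `semitones` (2^(s/12) frequency scaling) at fixed duration."""
    if semitones == 0:
        return EpochWaveform(
            epoch.samples.copy(), epoch.sample_rate, epoch.epoch_index
        )
    factor = 2.0 ** (semitones / 12.0)
    frac = Fraction(1.0 / factor).limit_denominator(200)
    y = resample_poly(epoch.samples, frac.numerator, frac.denominator)
    z = _phase_vocoder_stretch(y, len(epoch.samples))
    return EpochWaveform(z, epoch.sample_rate, epoch.epoch_index)


def random_pitch_shift(
    epoch: EpochWaveform, rng: np.random.Generator, max_semitones: float = 2.0
) -> EpochWaveform:
    return pitch_shift(epoch, rng.uniform(-max_semitones, max_semitones), rng)


# ---------------------------------------------------------------------------
# 40-epoch windows


WINDOW_EPOCHS = 40
LABELED_EPOCHS = 20
EDGE_EPOCHS = (WINDOW_EPOCHS - LABELED_EPOCHS) // 2  # 10 on each side


@dataclass
class StageWindow:
    """40 consecutive mel epochs; labels (if any) cover the middle 20.

    `mel` is stacked [40 x n_mels x n_frames]; `labels` is a length-20 array
    of stage names aligned to epochs start_epoch+10 .. start_epoch+29
    (0-based); `domain` is "source" or "target".
    """

    mel: np.ndarray
    labels: Optional[np.ndarray] = None
    domain: str = "source"
    start_epoch: int = 0

    def __post_init__(self):
        if self.mel.shape[0] != WINDOW_EPOCHS:
            raise ValueError(f"window must hold {WINDOW_EPOCHS} epochs")
        if self.labels is not None and len(self.labels) != LABELED_EPOCHS:
            raise ValueError(f"labels must cover the middle {LABELED_EPOCHS} epochs")

    @property
    def label_slice(self) -> slice:
        """Epoch indices (within the night) covered by the labels."""
        return slice(self.start_epoch + EDGE_EPOCHS,
                     self.start_epoch + EDGE_EPOCHS + LABELED_EPOCHS)


def windowize(
    epochs: Sequence[MelEpoch] | np.ndarray,
    labels: Optional[Sequence[str]] = None,
    stride: int = LABELED_EPOCHS,
    domain: str = "source",
) -> list[StageWindow]:
    """Slide a 40-epoch window across a night at `stride` epochs.

    With the default stride of 20 the middle label slices tile the night:
    epochs 10 .. N-11 (0-based) are each labeled by exactly one window.
    """
    if isinstance(epochs, np.ndarray):
        stacked = epochs
    else:
        stacked = np.stack([e.values for e in epochs])
    n = stacked.shape[0]
    if n < WINDOW_EPOCHS:
        raise ValueError(
            f"night too short to window: {n} epochs < {WINDOW_EPOCHS}"
        )
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels must align 1:1 with epochs")
    windows = []
    for start in range(0, n - WINDOW_EPOCHS + 1, stride):
        lab = None
        if labels is not None:
            lab = labels[start + EDGE_EPOCHS : start + EDGE_EPOCHS + LABELED_EPOCHS]
        windows.append(
            StageWindow(stacked[start : start + WINDOW_EPOCHS], lab, domain, start)
        )
    return windows


# ---------------------------------------------------------------------------
# Mel archives


def save_mel_archive(path, mel: np.ndarray, config: MelConfig) -> None:
    """Persist stacked mel epochs [n_epochs x n_mels x n_frames] + config."""
    np.savez_compressed(path, mel=mel, mel_config=np.bytes_(config.to_json()))


def load_mel_archive(path) -> tuple[np.ndarray, MelConfig]:
    with np.load(path) as z:
        mel = z["mel"]
        config = MelConfig.from_json(bytes(z["mel_config"]).decode())
    return mel, config
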