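"""Shared independent oracles for the test suite.

These deliberately recompute quantities from raw label pairs / first
principles, independent of the package's confusion-matrix or loss code
paths.
"""

from __future__ import annotations

import numpy as np


def pairwise_agreement(truth, pred, classes) -> dict:
    """Accuracy, kappa, macro F1, mean per-class sensitivity from raw pairs."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = len(truth)
    accuracy = float(np.mean(truth == pred))
    p_e = 0.0
    for c in classes:
        p_e += np.mean(truth == c) * np.mean(pred == c)
    kappa = None if abs(1 - p_e) < 1e-12 else (accuracy - p_e) / (1 - p_e)
    f1s, recalls = [], []
    for c in classes:
        tp = float(np.sum((truth == c) & (pred == c)))
        support = float(np.sum(truth == c))
        predicted = float(np.sum(pred == c))
        f1s.append(0.0 if support + predicted == 0 else 2 * tp / (support + predicted))
        if support > 0:
            recalls.append(tp / support)
    return {
        "accuracy": accuracy,
        "cohen_kappa": kappa,
        "macro_f1": float(np.mean(f1s)),
        "mean_per_class_sensitivity": float(np.mean(recalls)),
    }


def direct_jsd(p1, p2, p3) -> float:
    """Row-averaged three-way Jensen-Shannon divergence, straight formula."""
    p1, p2, p3 = (np.atleast_2d(np.asarray(p)) for p in (p1, p2, p3))
    m = (p1 + p2 + p3) / 3.0

    def kl(p, q):
        mask = p > 0
        return np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask])))

    vals = [
        (kl(p1[i], m[i]) + kl(p2[i], m[i]) + kl(p3[i], m[i])) / 3.0
        for i in range(p1.shape[0])
    ]
    return float(np.mean(vals))


def spectral_peak_hz(samples: np.ndarray, rate: int) -> float:
    """Frequency of the magnitude-spectrum maximum (Hann-windowed)."""
    spec = np.abs(np.fft.rfft(samples * np.hanning(len(samples))))
    return float(np.fft.rfftfreq(len(samples), 1.0 / rate)[np.argmax(spec)])


def band_energy(samples: np.ndarray, rate: int, lo: float, hi: float) -> float:
    from scipy.signal import stft

    f, _, Z = stft(samples, fs=rate, nperseg=512)
    sel = (f >= lo) & (f <= hi)
    return float(np.sum(np.abs(Z[sel]) ** 2))
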