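"""Hypnogram agreement and clinical sleep metrics.

Covers stage-scheme collapsing (5/4/3/2-class), confusion-matrix agreement
statistics (accuracy, Cohen kappa, macro F1, mean per-class sensitivity),
per-night sleep metrics (TST, SOL, SE, WASO, REM latency, stage portions),
Bland-Altman agreement between two per-night measurements, and a 2-D PCA
embedding of network features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .hypnogram import Hypnogram, SLEEP_STAGES, STAGES


# ---------------------------------------------------------------------------
# stage schemes


@dataclass(frozen=True)
class StageScheme:
    name: str
    mapping: dict  # 5-stage label -> scheme class
    classes: tuple  # fixed class order

    def collapse_label(self, stage: str) -> str:
        return self.mapping[stage]


SCHEMES: dict[str, StageScheme] = {
    "five": StageScheme("five", {s: s for s in STAGES}, STAGES),
    "four": StageScheme(
        "four",
        {"W": "W", "N1": "Light", "N2": "Light", "N3": "Deep", "REM": "REM"},
        ("W", "Light", "Deep", "REM"),
    ),
    "three": StageScheme(
        "three",
        {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM", "REM": "REM"},
        ("W", "NREM", "REM"),
    ),
    "two": StageScheme(
        "two",
        {"W": "W", "N1": "Sleep", "N2": "Sleep", "N3": "Sleep", "REM": "Sleep"},
        ("W", "Sleep"),
    ),
}


def get_scheme(name) -> StageScheme:
    key = {2: "two", 3: "three", 4: "four", 5: "five"}.get(name, name)
    if key not in SCHEMES:
        raise ValueError(f"unknown scheme {name!r}")
    return SCHEMES[key]


def collapse(h: Hypnogram, scheme: StageScheme | str | int) -> Hypnogram:
    """Map a 5-stage hypnogram onto a coarser scheme, preserving length."""
    sch = get_scheme(scheme) if not isinstance(scheme, StageScheme) else scheme
    stages = np.array([sch.collapse_label(s) for s in h.stages], dtype=object)
    return Hypnogram(stages, h.epoch_seconds, h.lights_off_index)


# ---------------------------------------------------------------------------
# confusion & agreement


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = truth, cols = prediction
    classes: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    pred: Hypnogram, truth: Hypnogram, scheme: StageScheme | str | int = "five"
) -> ConfusionMatrix:
    """Counts of (truth, prediction) pairs after collapsing both hypnograms."""
    sch = get_scheme(scheme) if not isinstance(scheme, StageScheme) else scheme
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: pred {len(pred)} vs truth {len(truth)}")
    classes = sch.classes
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth.stages, pred.stages):
        ti = index[sch.mapping.get(t, t)]
        pi = index[sch.mapping.get(p, p)]
        counts[ti, pi] += 1
    return ConfusionMatrix(counts, classes)


def agreement_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, Cohen kappa, macro F1, and mean per-class sensitivity.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals; with a
    degenerate p_e = 1 kappa is returned as None. A class with zero support
    contributes F1 = 0 to the macro mean and is excluded from mean per-class
    sensitivity (recall is undefined without true examples).
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(counts) / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    p_e = float(np.sum(row * col)) / total**2
    kappa = None if abs(1.0 - p_e) < 1e-12 else (accuracy - p_e) / (1.0 - p_e)

    f1s, recalls = [], []
    for i in range(len(cm.classes)):
        tp = counts[i, i]
        denom_f1 = row[i] + col[i]
        f1s.append(0.0 if denom_f1 == 0 else 2.0 * tp / denom_f1)
        if row[i] > 0:
            recalls.append(tp / row[i])
    return {
        "accuracy": float(accuracy),
        "cohen_kappa": None if kappa is None else float(kappa),
        "macro_f1": float(np.mean(f1s)),
        "mean_per_class_sensitivity": float(np.mean(recalls)),
    }


# ---------------------------------------------------------------------------
# per-night sleep metrics


@dataclass
class SleepMetrics:
    """Clinical per-night summary, minutes unless noted.

    TST: total time in any sleep stage. SOL: lights-off to first sleep epoch.
    SE: TST / recording time, percent. WASO: wake between first and last
    sleep epoch. REM latency: first sleep epoch to first REM epoch. Stage
    portions: per-stage time / recording time, percent. SOL/WASO/REM latency
    are None when undefined (no sleep, or no REM).
    """

    tst: float
    se: float
    sol: Optional[float]
    waso: Optional[float]
    rem_latency: Optional[float]
    portions: dict[str, float] = field(default_factory=dict)
    recording_minutes: float = 0.0


def _is_sleep(stage: str) -> bool:
    return stage in SLEEP_STAGES or stage in {"Sleep", "NREM", "REM", "Light", "Deep"}


def sleep_metrics(h: Hypnogram) -> SleepMetrics:
    """Compute the per-night metrics from a hypnogram (any scheme).

    Works on 5-stage or collapsed hypnograms: any non-W class counts as
    sleep; REM latency requires an explicit REM class.
    """
    epm = h.epoch_seconds / 60.0  # minutes per epoch
    stages = h.stages
    n = len(stages)
    sleep_mask = np.array([_is_sleep(s) for s in stages])
    recording = n * epm
    tst = float(sleep_mask.sum()) * epm
    se = 100.0 * tst / recording

    sol = waso = rem_latency = None
    if sleep_mask.any():
        first = int(np.argmax(sleep_mask))
        last = n - 1 - int(np.argmax(sleep_mask[::-1]))
        sol = (first - h.lights_off_index) * epm
        waso = float((~sleep_mask[first : last + 1]).sum()) * epm
        rem_idx = np.nonzero(stages == "REM")[0]
        if len(rem_idx) > 0:
            rem_latency = (int(rem_idx[0]) - first) * epm

    portions = {}
    for cls in dict.fromkeys(stages):  # preserve appearance order
        portions[cls] = 100.0 * float(np.sum(stages == cls)) / n
    return SleepMetrics(tst, se, sol, waso, rem_latency, portions, recording)


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low: float
    ci_high: float
    n: int


def bland_altman(pairs: Sequence[tuple[float, float]]) -> BlandAltmanResult:
    """Agreement between two per-night measurements.

    Differences are test - reference; limits of agreement are
    mean +/- 1.96 SD (SD with n-1 denominator); the 95% CI of the mean
    difference uses the t distribution with n-1 df.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (reference, test) pairs")
    diffs = arr[:, 1] - arr[:, 0]
    n = len(diffs)
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
    )


# ---------------------------------------------------------------------------
# PCA feature embedding


def pca_embed(
    features: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Project per-window feature summaries onto the top principal axes.

    `features` is [n_samples x time-steps x dims] (averaged over time-steps)
    or already [n_samples x dims]. Returns (coordinates, explained-variance
    fractions, non-increasing).
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 3:
        x = x.mean(axis=1)
    if x.shape[0] < n_components:
        raise ValueError("fewer samples than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_
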