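"""Sleep stages and hypnograms.

A hypnogram is the per-night sequence of 30-second-epoch stage labels in
{W, N1, N2, N3, REM}; it is the currency of both ground truth and model
predictions. CSV files use a 1-based `epoch_index,stage` layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
SLEEP_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3", "REM"})


def validate_stage(stage: str) -> str:
    if stage not in STAGE_TO_INDEX:
        raise ValueError(f"unknown sleep stage {stage!r}; expected one of {STAGES}")
    return stage


@dataclass
class Hypnogram:
    """Ordered per-epoch stage labels with epoch duration and lights-off index.

    `lights_off_index` is the 0-based epoch at which lights were turned off;
    for audio-only home recordings it defaults to the recording start.
    `stages` may use a collapsed scheme (e.g. NREM), so stage validity is
    only enforced by constructors that require the 5-stage scheme.
    """

    stages: np.ndarray
    epoch_seconds: float = 30.0
    lights_off_index: int = 0

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if len(self.stages) == 0:
            raise ValueError("empty hypnogram")
        if not 0 <= self.lights_off_index < len(self.stages):
            raise ValueError("lights_off_index outside recording")

    def __len__(self) -> int:
        return len(self.stages)

    def indices(self) -> np.ndarray:
        """Stage indices in canonical (W, N1, N2, N3, REM) order."""
        return np.array([STAGE_TO_INDEX[s] for s in self.stages], dtype=np.int64)

    @classmethod
    def from_indices(cls, idx: Sequence[int], **kw) -> "Hypnogram":
        return cls(np.array([STAGES[i] for i in idx], dtype=object), **kw)


def write_hypnogram_csv(path, h: Hypnogram) -> None:
    """One row per 30-s epoch, 1-based epoch_index."""
    df = pd.DataFrame(
        {"epoch_index": np.arange(1, len(h) + 1), "stage": list(h.stages)}
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_hypnogram_csv(path, epoch_seconds: float = 30.0,
                       lights_off_index: int = 0) -> Hypnogram:
    df = pd.read_csv(path, dtype={"stage": str})
    if list(df.columns[:2]) != ["epoch_index", "stage"]:
        raise ValueError("hypnogram CSV must have header 'epoch_index,stage'")
    df = df.sort_values("epoch_index")
    for s in df["stage"]:
        validate_stage(s)
    return Hypnogram(
        df["stage"].to_numpy(dtype=object), epoch_seconds, lights_off_index
    )
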