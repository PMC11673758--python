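"""Clip data model and manifest CSV round-trip.

A clip is a contiguous frame interval on one cage side.  Stage 1 emits
``likely_grooming`` clips; human review turns them into ``confirmed_*``
labels; the classifier emits ``predicted_*`` labels.  At 1 frame/s the
duration in seconds equals the frame count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = ["Clip", "LABELS", "write_manifest", "read_manifest"]

LABELS = (
    "likely_grooming",
    "confirmed_grooming",
    "confirmed_non_grooming",
    "predicted_grooming",
    "predicted_non_grooming",
)

#: regimes a synthetic ground-truth clip can carry
REGIMES = ("motionless", "grooming", "drastic")


@dataclass(frozen=True)
class Clip:
    """A contiguous frame interval [start_frame, end_frame) on one cage side."""

    dataset: str
    side: str
    start_frame: int
    end_frame: int
    label: str = "likely_grooming"

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError(
                f"empty clip: [{self.start_frame}, {self.end_frame})")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def duration_s(self) -> int:
        """Clip duration in seconds (= frames at 1 fps)."""
        return self.end_frame - self.start_frame

    @property
    def clip_id(self) -> str:
        return f"{self.dataset}:{self.side}:{self.start_frame}-{self.end_frame}"

    def with_label(self, label: str) -> "Clip":
        return replace(self, label=label)


def write_manifest(clips: list[Clip], path: str | Path) -> None:
    """Write a clip manifest CSV: dataset,side,start_frame,end_frame,duration_s,label."""
    df = pd.DataFrame(
        [
            {
                "dataset": c.dataset,
                "side": c.side,
                "start_frame": c.start_frame,
                "end_frame": c.end_frame,
                "duration_s": c.duration_s,
                "label": c.label,
            }
            for c in clips
        ],
        columns=["dataset", "side", "start_frame", "end_frame", "duration_s", "label"],
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[Clip]:
    df = pd.read_csv(path)
    return [
        Clip(
            dataset=str(r.dataset),
            side=str(r.side),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
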