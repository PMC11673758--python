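"""Stage 1: motion-index time series and likely-grooming clip extraction.

The stage-1 screen reduces a day-long recording to a small set of "likely
grooming" clips using only consecutive-frame differences:

1. ``frame_difference`` — for each consecutive frame pair, the fraction of
   pixels whose gray-level change exceeds a sensor-noise tolerance ``alpha``:

       dp(t) = (1 / (W*H)) * #{(i, j) : |I_t(i,j) - I_{t+1}(i,j)| > alpha}

2. ``moving_average`` — a 50%-overlapping moving window (w = 10 frames,
   step k = 5) averages dp into a per-window motion index Dp(s).
3. ``grooming_indicator`` — Dp strictly between theta_min = 0.009 and
   theta_max = 0.08 flags the window as likely grooming: below the band the
   animal is at rest, above it the motion is too large (locomotion).
4. ``smooth_indicator`` — a 3-point median filter applied twice removes
   isolated single-window interruptions in either direction.
5. ``extract_clips`` — each maximal run of S flagged windows becomes one
   clip of (S-1)*k + w frames; clips shorter than 10 frames are dropped.

All indices are 0-based; window s covers dp entries [s*k, s*k + w).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .clips import Clip
from .video_io import FrameSequence

__all__ = [
    "MotionParams",
    "MotionTrace",
    "frame_difference",
    "moving_average",
    "grooming_indicator",
    "smooth_indicator",
    "extract_clips",
    "scan_recording",
    "retained_fraction",
]


@dataclass(frozen=True)
class MotionParams:
    """Stage-1 parameters.

    ``alpha`` is the gray-level tolerance below which a pixel change is
    attributed to sensor noise (default 10 of 255).  ``window_w``/``step_k``
    define the 50%-overlapping moving window; ``theta_min``/``theta_max``
    bracket the likely-grooming band of the windowed motion index.
    """

    alpha: float = 10.0
    window_w: int = 10
    step_k: int = 5
    theta_min: float = 0.009
    theta_max: float = 0.08
    min_clip_frames: int = 10

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.window_w >= self.step_k >= 1:
            raise ValueError("need window_w >= step_k >= 1")
        if not 0 < self.theta_min < self.theta_max:
            raise ValueError("need 0 < theta_min < theta_max")
        if self.min_clip_frames < 1:
            raise ValueError("min_clip_frames must be >= 1")


@dataclass(frozen=True)
class MotionTrace:
    """Per-recording motion series: dp (per frame pair), Dp/gp/gp_smooth (per window)."""

    dp: np.ndarray
    Dp: np.ndarray
    gp: np.ndarray
    gp_smooth: np.ndarray
    params: MotionParams

    def frame_table(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(len(self.dp)), "dp": self.dp})

    def window_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": np.arange(len(self.Dp)),
                "Dp": self.Dp,
                "gp": self.gp,
                "gp_smooth": self.gp_smooth,
            }
        )


def frame_difference(seq: FrameSequence, alpha: float = 10.0) -> np.ndarray:
    """Fraction of super-threshold pixels for every consecutive frame pair.

    Streams through the sequence keeping a single previous frame in memory;
    returns a length T-1 array with values in [0, 1].
    """
    dp = []
    prev = None
    for frame in seq:
        if prev is not None:
            if frame.shape != prev.shape:
                raise ValueError(
                    f"frame size changed mid-sequence: {prev.shape} -> {frame.shape}")
            diff = np.abs(prev.astype(np.int16) - frame.astype(np.int16))
            dp.append(np.count_nonzero(diff > alpha) / diff.size)
        prev = frame
    if not dp:
        raise ValueError("need at least 2 frames to compute frame differences")
    return np.asarray(dp)


def moving_average(dp: np.ndarray, params: MotionParams) -> np.ndarray:
    """Windowed mean of dp: Dp(s) = mean dp[s*k : s*k + w], full windows only."""
    dp = np.asarray(dp, dtype=float)
    w, k = params.window_w, params.step_k
    if len(dp) < w:
        raise ValueError(f"motion trace of {len(dp)} entries is shorter than one "
                         f"window (w = {w}); recording too short")
    n_windows = (len(dp) - w) // k + 1
    csum = np.concatenate([[0.0], np.cumsum(dp)])
    starts = np.arange(n_windows) * k
    return (csum[starts + w] - csum[starts]) / w


def grooming_indicator(Dp: np.ndarray, params: MotionParams) -> np.ndarray:
    """Binary likely-grooming flag: 1 iff theta_min < Dp(s) < theta_max (strict)."""
    Dp = np.asarray(Dp, dtype=float)
    return ((params.theta_min < Dp) & (Dp < params.theta_max)).astype(np.int64)


def smooth_indicator(gp: np.ndarray) -> np.ndarray:
    """Two passes of a width-3 median filter with replicate end-padding.

    Removes isolated single-window 1s and 0s so brief pauses or jerks do not
    fragment an otherwise continuous episode.
    """
    gp = np.asarray(gp, dtype=np.int64)
    if len(gp) == 0:
        raise ValueError("empty indicator series")
    out = median_filter(gp, size=3, mode="nearest")
    return median_filter(out, size=3, mode="nearest")


def extract_clips(gp_smooth: np.ndarray, params: MotionParams, side: str,
                  dataset: str = "recording") -> list[Clip]:
    """Turn maximal runs of flagged windows into likely-grooming clips.

    A run of windows [s_first, s_last] spans frames
    [s_first*k, s_last*k + w), i.e. (S-1)*k + w frames for a run of length S.
    Runs spanning fewer than ``min_clip_frames`` frames are excluded.
    """
    g = np.asarray(gp_smooth, dtype=np.int64)
    w, k = params.window_w, params.step_k
    clips: list[Clip] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], g, [0]])))
    for run_start, run_end in zip(edges[::2], edges[1::2]):  # [run_start, run_end)
        s_first, s_last = run_start, run_end - 1
        start_frame = s_first * k
        end_frame = s_last * k + w
        if end_frame - start_frame >= params.min_clip_frames:
            clips.append(Clip(dataset, side, int(start_frame), int(end_frame),
                              label="likely_grooming"))
    return clips


def scan_recording(seq: FrameSequence, params: MotionParams | None = None,
                   dataset: str = "recording") -> tuple[MotionTrace, list[Clip]]:
    """Run the full stage-1 screen on one cage side of a recording."""
    params = params or MotionParams()
    dp = frame_difference(seq, params.alpha)
    Dp = moving_average(dp, params)
    gp = grooming_indicator(Dp, params)
    gs = smooth_indicator(gp)
    clips = extract_clips(gs, params, side=seq.side, dataset=dataset)
    return MotionTrace(dp=dp, Dp=Dp, gp=gp, gp_smooth=gs, params=params), clips


def retained_fraction(clips: list[Clip], total_frames: int) -> float:
    """Fraction of the recording covered by (disjoint) extracted clips."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    covered = np.zeros(total_frames, dtype=bool)
    for c in clips:
        covered[c.start_frame : min(c.end_frame, total_frames)] = True
    return float(covered.mean())
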