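"""Convert a clip into classifier inputs: per-segment 3-channel images and
stacked optical-flow fields.

A clip is divided into ``Ns`` contiguous segments of (near-)equal length.
From each segment:

* three frames are drawn at random (without replacement when the segment has
  at least three frames), sorted chronologically, and stacked as the three
  channels of one image ``A_n`` — the monochrome frames fill the channels
  directly;
* a run of ``Nf + 1`` consecutive frames starting at a random in-segment
  offset yields ``Nf`` dense optical-flow fields whose x- and y-components
  are stacked separately (``O_nx``, ``O_ny``).  Segments shorter than
  ``Nf + 1`` frames are padded by repeating the final frame, so the padded
  pairs contribute identically zero flow.

Images are scaled to [0, 1]; flow is clamped to +/-``flow_clamp_px`` pixels
and rescaled to [-1, 1] before network ingestion.  All sampling randomness
derives from a per-(clip, epoch) seed so training batches are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.registration import optical_flow_ilk, optical_flow_tvl1
from skimage.transform import resize

from .clips import Clip
from .video_io import FrameSequence

__all__ = [
    "SamplerParams",
    "ClipSample",
    "segment_clip",
    "sample_rgb_stack",
    "sample_flow_stack",
    "sample_clip",
    "stack_samples",
    "rng_for_clip",
    "FLOW_ESTIMATORS",
]


def _flow_ilk(f0: np.ndarray, f1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Iterative Lucas-Kanade dense flow; returns (flow_x, flow_y) in px."""
    v, u = optical_flow_ilk(f0.astype(np.float64) / 255.0,
                            f1.astype(np.float64) / 255.0, radius=5)
    return u, v


def _flow_tvl1(f0: np.ndarray, f1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v, u = optical_flow_tvl1(f0.astype(np.float64) / 255.0,
                             f1.astype(np.float64) / 255.0)
    return u, v


#: pluggable dense flow estimators: id -> callable(frame_t, frame_t1) -> (x, y)
FLOW_ESTIMATORS: dict[str, Callable] = {"ilk": _flow_ilk, "tvl1": _flow_tvl1}


@dataclass(frozen=True)
class SamplerParams:
    """Clip sampling parameters: Ns segments, Nf-deep flow stacks."""

    n_segments: int = 3
    flow_stack_len: int = 10
    flow_estimator: str = "ilk"
    output_size: tuple[int, int] | None = None   # (h, w); None keeps native size
    flow_clamp_px: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.flow_stack_len < 1:
            raise ValueError("flow_stack_len must be >= 1")
        if self.flow_estimator not in FLOW_ESTIMATORS:
            raise ValueError(
                f"unknown flow estimator {self.flow_estimator!r}; "
                f"available: {sorted(FLOW_ESTIMATORS)}")


@dataclass(frozen=True)
class ClipSample:
    """Network-ready representation of one clip.

    ``images``: (Ns, 3, h, w) in [0, 1]; ``flow_x``/``flow_y``: (Ns, Nf, h, w)
    in [-1, 1] after clamping.  ``provenance`` records the clip id and the
    frame indices / offsets actually drawn.
    """

    images: np.ndarray
    flow_x: np.ndarray
    flow_y: np.ndarray
    provenance: dict = field(default_factory=dict)


def rng_for_clip(clip_id: str, seed: int, epoch: int = 0) -> np.random.Generator:
    """Reproducible per-(clip, epoch) random stream."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(clip_id.encode()), epoch]))


def segment_clip(clip: Clip | tuple[int, int], n_segments: int) -> list[tuple[int, int]]:
    """Split a clip into Ns contiguous ranges whose lengths differ by <= 1 frame."""
    if isinstance(clip, Clip):
        start, end = clip.start_frame, clip.end_frame
    else:
        start, end = clip
    if end <= start:
        raise ValueError("clip must contain at least one frame")
    parts = np.array_split(np.arange(start, end), n_segments)
    return [(int(p[0]), int(p[-1]) + 1) for p in parts if len(p)]


def _fetch(seq: FrameSequence, start: int, stop: int,
           output_size: tuple[int, int] | None) -> np.ndarray:
    frames = seq.get_frames(start, stop).astype(np.float64)
    if output_size is not None and frames.shape[1:] != tuple(output_size):
        frames = np.stack([
            resize(f, output_size, anti_aliasing=True, preserve_range=True)
            for f in frames
        ])
    return frames


def sample_rgb_stack(seq: FrameSequence, frame_range: tuple[int, int],
                     rng: np.random.Generator,
                     output_size: tuple[int, int] | None = None) -> np.ndarray:
    """Draw 3 frames from a segment and stack them chronologically as channels.

    Returns ``(stack, indices)``: the (3, h, w) image in [0, 1] and the
    ascending absolute frame indices drawn (without replacement unless the
    segment has fewer than 3 frames).
    """
    start, end = frame_range
    n = end - start
    if n < 1:
        raise ValueError("empty segment")
    replace = n < 3
    idx = np.sort(rng.choice(n, size=3, replace=replace)) + start
    frames = _fetch(seq, int(idx[0]), int(idx[-1]) + 1, output_size)
    stack = np.stack([frames[i - idx[0]] for i in idx])
    return stack / 255.0, idx


def sample_flow_stack(seq: FrameSequence, frame_range: tuple[int, int], n_flow: int,
                      estimator: str, rng: np.random.Generator,
                      output_size: tuple[int, int] | None = None,
                      clamp_px: float = 20.0):
    """Stacked dense optical flow from Nf+1 consecutive frames at a random offset.

    Returns ``(flow_x, flow_y, offset)`` with both stacks of shape
    (Nf, h, w), clamped to +/-clamp_px and rescaled to [-1, 1].
    """
    start, end = frame_range
    n = end - start
    if n < 2:
        raise ValueError("flow sampling needs a segment of at least 2 frames")
    flow_fn = FLOW_ESTIMATORS[estimator]
    max_offset = max(0, n - (n_flow + 1))
    offset = int(rng.integers(0, max_offset + 1))
    stop = min(end, start + offset + n_flow + 1)
    frames = _fetch(seq, start + offset, stop, output_size)
    h, w = frames.shape[1:]
    fx = np.zeros((n_flow, h, w))
    fy = np.zeros((n_flow, h, w))
    n_pairs = min(n_flow, len(frames) - 1)
    for i in range(n_pairs):
        fx[i], fy[i] = flow_fn(frames[i], frames[i + 1])
    # segments shorter than Nf+1 frames: final frame repeated => zero flow pads
    fx = np.clip(fx, -clamp_px, clamp_px) / clamp_px
    fy = np.clip(fy, -clamp_px, clamp_px) / clamp_px
    return fx, fy, offset


def sample_clip(seq: FrameSequence, clip: Clip, params: SamplerParams,
                epoch: int = 0) -> ClipSample:
    """Full sampling of one clip into a :class:`ClipSample`."""
    rng = rng_for_clip(clip.clip_id, params.seed, epoch)
    segments = segment_clip(clip, params.n_segments)
    images, fxs, fys = [], [], []
    frame_idx, offsets = [], []
    for seg in segments:
        stack, idx = sample_rgb_stack(seq, seg, rng, params.output_size)
        images.append(stack)
        frame_idx.append(idx.tolist())
        fx, fy, off = sample_flow_stack(
            seq, seg, params.flow_stack_len, params.flow_estimator, rng,
            params.output_size, params.flow_clamp_px)
        fxs.append(fx)
        fys.append(fy)
        offsets.append(off)
    return ClipSample(
        images=np.stack(images),
        flow_x=np.stack(fxs),
        flow_y=np.stack(fys),
        provenance={
            "clip_id": clip.clip_id,
            "epoch": epoch,
            "segments": segments,
            "frame_indices": frame_idx,
            "flow_offsets": offsets,
        },
    )


def stack_samples(samples: list[ClipSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch a list of clip samples into (images, flow_x, flow_y) arrays."""
    return (
        np.stack([s.images for s in samples]),
        np.stack([s.flow_x for s in samples]),
        np.stack([s.flow_y for s in samples]),
    )
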