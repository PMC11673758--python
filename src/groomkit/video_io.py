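"""Memory-bounded readers for long monochrome recordings.

Recordings arrive either as a standard video container or as a directory of
sequentially numbered grayscale images, one frame per second.  Each frame
shows two side-by-side cages; analysis always runs on one cage half, so every
reader carries a ``side`` and yields only the corresponding columns.

Conventions
-----------
* pixels are 0-based, row-major, 8-bit grayscale in [0, 255];
* frame indices are 0-based internally (human-facing reports add 1);
* the left half is columns ``[0, W/2)``, the right half ``[W/2, W)`` —
  a left-closed/right-open vertical midline split.  Rigs with an off-centre
  divider can pass an explicit ``split_col``.

Readers are pure: iterating twice yields identical frames, and no reader
ever materialises a full day of video in memory.
"""

from __future__ import annotations

import os
import re
from collections.abc import Iterator
from pathlib import Path

import numpy as np

__all__ = [
    "FrameSequence",
    "ArraySequence",
    "DirectorySequence",
    "VideoFileSequence",
    "open_recording",
    "write_frames",
    "split_frame",
]

SIDES = ("left", "right")

_VIDEO_EXTS = {".avi", ".mp4", ".mov", ".mkv", ".mpg", ".mpeg", ".wmv"}
_IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def _to_gray_u8(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit grayscale; pass grayscale through."""
    arr = np.asarray(frame)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def split_frame(frame: np.ndarray, side: str, split_col: int | None = None) -> np.ndarray:
    """Return one cage half of a full two-cage frame."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    w = frame.shape[1]
    if split_col is None:
        if w % 2:
            raise ValueError(f"frame width {w} is odd; pass an explicit split_col")
        split_col = w // 2
    return frame[:, :split_col] if side == "left" else frame[:, split_col:]


class FrameSequence:
    """Ordered 8-bit grayscale frames for one cage side.

    Subclasses implement ``_iter_full_frames`` (full two-cage frames) or
    override :meth:`iter_frames` directly.  ``len(seq)`` is the frame count T;
    ``seq.frame_size`` is (width, height) of the emitted (side-split) frames.
    """

    side: str = "left"
    source: str = "<memory>"
    fps: float = 1.0
    split_col: int | None = None

    def __len__(self) -> int:
        raise NotImplementedError

    @property
    def frame_size(self) -> tuple[int, int]:
        frame = next(iter(self))
        return frame.shape[1], frame.shape[0]

    def _iter_full_frames(self) -> Iterator[np.ndarray]:
        raise NotImplementedError

    def iter_frames(self) -> Iterator[np.ndarray]:
        for frame in self._iter_full_frames():
            yield split_frame(_to_gray_u8(frame), self.side, self.split_col)

    def __iter__(self) -> Iterator[np.ndarray]:
        return self.iter_frames()

    def get_frames(self, start: int, stop: int) -> np.ndarray:
        """Materialise frames [start, stop) as a (n, H, W) uint8 array."""
        if not 0 <= start < stop <= len(self):
            raise IndexError(f"frame range [{start}, {stop}) outside [0, {len(self)})")
        out = []
        for t, frame in enumerate(self):
            if t >= stop:
                break
            if t >= start:
                out.append(frame)
        return np.stack(out)


class ArraySequence(FrameSequence):
    """Frames held in memory; used for short clips and tests."""

    def __init__(self, frames: np.ndarray, side: str = "left", source: str = "<memory>",
                 fps: float = 1.0, presplit: bool = True, split_col: int | None = None):
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(frames) == 0:
            raise ValueError(f"{source}: zero frames")
        self._frames = frames
        self.side = side
        self.source = source
        self.fps = fps
        self._presplit = presplit
        self.split_col = split_col

    def __len__(self) -> int:
        return len(self._frames)

    def iter_frames(self) -> Iterator[np.ndarray]:
        for frame in self._frames:
            frame = _to_gray_u8(frame)
            if not self._presplit:
                frame = split_frame(frame, self.side, self.split_col)
            yield frame


class DirectorySequence(FrameSequence):
    """A directory of sequentially numbered grayscale images.

    Time order is defined by lexicographic sort of the (zero-padded) numeric
    filenames, the dialect the synthetic generator writes.
    """

    def __init__(self, path: str | Path, side: str, fps: float = 1.0,
                 split_col: int | None = None):
        import imageio.v3 as iio

        self._iio = iio
        self.path = Path(path)
        files = sorted(
            f for f in os.listdir(self.path)
            if Path(f).suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise FileNotFoundError(f"{path}: no image frames found")
        self._files = files
        self.side = side
        self.source = str(path)
        self.fps = fps
        self.split_col = split_col
        first = iio.imread(self.path / files[0])
        w = np.asarray(first).shape[1]
        if split_col is None and w % 2:
            raise ValueError(f"{path}: frame width {w} is odd; pass split_col")

    def __len__(self) -> int:
        return len(self._files)

    def _iter_full_frames(self) -> Iterator[np.ndarray]:
        for name in self._files:
            yield self._iio.imread(self.path / name)


class VideoFileSequence(FrameSequence):
    """A standard video container read frame-by-frame through imageio."""

    def __init__(self, path: str | Path, side: str, fps: float = 1.0,
                 split_col: int | None = None):
        import imageio.v3 as iio

        self._iio = iio
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(str(path))
        self.side = side
        self.source = str(path)
        self.fps = fps
        self.split_col = split_col
        try:
            props = iio.improps(self.path, plugin="pyav")
        except Exception:
            props = iio.improps(self.path)
        n = props.n_images
        if n is None or n <= 0:
            n = sum(1 for _ in self._iter_full_frames())
        if n == 0:
            raise ValueError(f"{path}: zero frames")
        self._n = int(n)
        first = next(self._iter_full_frames())
        w = np.asarray(first).shape[1]
        if split_col is None and w % 2:
            raise ValueError(f"{path}: frame width {w} is odd; pass split_col")

    def __len__(self) -> int:
        return self._n

    def _iter_full_frames(self) -> Iterator[np.ndarray]:
        yield from self._iio.imiter(self.path)


def open_recording(path: str | Path, side: str, fps: float = 1.0,
                   split_col: int | None = None) -> FrameSequence:
    """Open a recording (video container or frame directory) for one cage side.

    Parameters
    ----------
    path
        Video file or directory of numbered grayscale images.
    side
        ``"left"`` (experimental cage) or ``"right"`` (control cage).
    split_col
        Column index of the cage divider; defaults to the frame midline.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    p = Path(path)
    if p.is_dir():
        return DirectorySequence(p, side=side, fps=fps, split_col=split_col)
    if p.suffix.lower() in _VIDEO_EXTS:
        return VideoFileSequence(p, side=side, fps=fps, split_col=split_col)
    raise ValueError(f"{path}: not a frame directory or recognised video container")


def write_frames(seq: FrameSequence | np.ndarray, out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Write frames as zero-padded 8-bit grayscale PNGs (the directory dialect)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = seq if isinstance(seq, np.ndarray) else seq.iter_frames()
    n = len(seq)
    width = max(6, len(str(n)))
    paths = []
    for t, frame in enumerate(frames):
        path = out / f"{prefix}_{t:0{width}d}.png"
        iio.imwrite(path, _to_gray_u8(frame))
        paths.append(path)
    return paths
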