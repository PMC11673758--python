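"""Ground-truthed synthetic two-cage recordings.

The generator emulates the recording geometry the pipeline is built for:
monochrome top-view frames at 1 frame/s, 320x240 px, each frame split into a
left (experimental) and right (control) cage half.  Each cage contains one
rat-shaped blob — a filled, textured ellipse — whose motion follows one of
three regimes:

``motionless``
    the blob does not move; only per-frame sensor noise differs.
``grooming``
    a small "head" patch of the blob oscillates with 1-3 px amplitude,
    emulating the small-amplitude repetitive motion of self-grooming.
``drastic``
    the whole blob translates by >= 10 px per frame (locomotion).

The blob carries a fixed high-contrast random texture so that a k-px shift
changes essentially every pixel the moving part covers; the fraction of
changed pixels is then controlled by the area of the moving part, which is
what the stage-1 thresholds respond to.  With the default geometry the
grooming regime changes ~2% of a cage half per frame pair — strictly inside
the stage-1 detection band — while drastic locomotion changes ~15% (above
the band) and motionless regimes change nothing beyond sensor noise.

All randomness flows from the single spec-level seed through named
``numpy.random.Generator`` streams; a fixed seed gives bit-identical frames,
and frames are rendered lazily so day-long scenarios never occupy memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clips import Clip, write_manifest
from .video_io import ArraySequence, FrameSequence, write_frames

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "SyntheticSequence",
    "render_video",
    "write_recording",
    "sample_duration_dataset",
    "make_classification_dataset",
]

REGIMES = ("motionless", "grooming", "drastic")
_SIDE_INDEX = {"left": 0, "right": 1}


@dataclass(frozen=True)
class ScenarioSpec:
    """Description of one synthetic two-cage recording.

    Parameters
    ----------
    duration_s
        Total number of frames (1 frame per second).
    frame_size
        Full-frame (width, height) in px; both must be even so the frame
        splits into equal cage halves.  Default 320x240.
    regimes
        Mapping ``side -> list of (regime, start_s, end_s)`` with
        non-overlapping, in-range intervals; seconds not covered by any
        interval default to ``motionless``.
    noise_sigma
        Per-frame additive Gaussian sensor noise, gray levels of 255.
        Default 2.0, comfortably below the stage-1 gray-level tolerance.
    seed
        Master seed; every random stream derives from it.
    grooming_amplitude_px
        Head-patch oscillation amplitude (1-3 px). Default 2.
    drastic_step_px
        Whole-blob translation per frame in the drastic regime (>= 10 px).
    """

    duration_s: int
    frame_size: tuple[int, int] = (320, 240)
    regimes: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    noise_sigma: float = 2.0
    seed: int = 0
    grooming_amplitude_px: int = 2
    drastic_step_px: int = 12

    def __post_init__(self):
        w, h = self.frame_size
        if w % 2 or h % 2:
            raise ValueError(f"frame size {w}x{h} must have even width and height")
        if self.duration_s < 2:
            raise ValueError("duration_s must be at least 2 frames")
        if not 1 <= self.grooming_amplitude_px <= 3:
            raise ValueError("grooming amplitude must be 1-3 px")
        if self.drastic_step_px < 10:
            raise ValueError("drastic regime must translate >= 10 px/frame")
        for side, intervals in self.regimes.items():
            if side not in _SIDE_INDEX:
                raise ValueError(f"unknown side {side!r}")
            prev_end = None
            for regime, start, end in sorted(intervals, key=lambda r: r[1]):
                if regime not in REGIMES:
                    raise ValueError(f"unknown regime {regime!r}")
                if not 0 <= start < end <= self.duration_s:
                    raise ValueError(
                        f"regime interval [{start}, {end}) outside [0, {self.duration_s})")
                if prev_end is not None and start < prev_end:
                    raise ValueError(
                        f"overlapping regime intervals on side {side!r} at t={start}")
                prev_end = end

    def regime_sequence(self, side: str) -> list[str]:
        """Per-frame regime labels for one side (gaps are motionless)."""
        seq = ["motionless"] * self.duration_s
        for regime, start, end in self.regimes.get(side, []):
            for t in range(start, end):
                seq[t] = regime
        return seq


@dataclass(frozen=True)
class GroundTruth:
    """True per-frame regimes and regime clips for a rendered scenario."""

    regimes: dict[str, list[str]]          # side -> per-frame regime labels
    clips: list[Clip]                      # maximal runs, label = regime name

    def frames_of(self, side: str, regime: str) -> np.ndarray:
        """0-based frame indices of one regime on one side."""
        seq = self.regimes[side]
        return np.flatnonzero(np.asarray(seq) == regime)


def _regime_clips(spec: ScenarioSpec, dataset: str) -> list[Clip]:
    clips = []
    for side in ("left", "right"):
        seq = spec.regime_sequence(side)
        start = 0
        for t in range(1, len(seq) + 1):
            if t == len(seq) or seq[t] != seq[start]:
                clips.append(Clip(dataset, side, start, t, label=seq[start]))
                start = t
    return clips


class _CageModel:
    """Geometry, texture and motion path of one cage half."""

    def __init__(self, spec: ScenarioSpec, side: str):
        w, h = spec.frame_size
        self.w_half, self.h = w // 2, h
        self.side = side
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, _SIDE_INDEX[side], 7]))

        # static cage background: dark bedding with fixed low-contrast speckle
        self.background = np.clip(
            60.0 + rng.normal(0.0, 3.0, (self.h, self.w_half)), 0, 255)

        # body: filled ellipse, high-contrast fixed texture
        ax = max(4, round(0.31 * self.w_half))
        ay = max(4, round(0.15 * self.h))
        yy, xx = np.mgrid[-ay : ay + 1, -ax : ax + 1]
        self.body_mask = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0
        self.body_tex = rng.uniform(80.0, 230.0, self.body_mask.shape)
        self.ax, self.ay = ax, ay

        # head patch: smaller textured disc near the front of the body
        pr = max(2, round(0.095 * self.w_half))
        pyy, pxx = np.mgrid[-pr : pr + 1, -pr : pr + 1]
        self.patch_mask = pxx**2 + pyy**2 <= pr**2
        self.patch_tex = rng.uniform(30.0, 220.0, self.patch_mask.shape)
        self.pr = pr
        self.head_dx = max(1, round(0.5 * ax))  # patch centre offset from body centre

        # motion path: x position per frame (ping-pong in drastic regimes)
        regimes = spec.regime_sequence(side)
        margin = ax + self.pr + spec.grooming_amplitude_px + 2
        lo = margin
        hi = max(lo + 1, self.w_half - margin)
        x = (lo + hi) // 2
        direction = 1
        xs = np.empty(spec.duration_s, dtype=np.int64)
        head = np.zeros(spec.duration_s, dtype=np.int64)
        for t, regime in enumerate(regimes):
            if regime == "drastic":
                step = spec.drastic_step_px
                if x + direction * step > hi or x + direction * step < lo:
                    direction = -direction
                x = int(np.clip(x + direction * step, lo, hi))
            elif regime == "grooming":
                head[t] = spec.grooming_amplitude_px * (t % 2)
            xs[t] = x
        self.xs = xs
        self.head_offset = head
        self.cy = self.h // 2

    def _stamp(self, frame: np.ndarray, cx: int, cy: int,
               mask: np.ndarray, tex: np.ndarray) -> None:
        mh, mw = mask.shape
        top, left = cy - mh // 2, cx - mw // 2
        r0, r1 = max(0, top), min(self.h, top + mh)
        c0, c1 = max(0, left), min(self.w_half, left + mw)
        mr0, mc0 = r0 - top, c0 - left
        sub = mask[mr0 : mr0 + (r1 - r0), mc0 : mc0 + (c1 - c0)]
        frame[r0:r1, c0:c1][sub] = tex[mr0 : mr0 + (r1 - r0), mc0 : mc0 + (c1 - c0)][sub]

    def render(self, t: int, seed: int, noise_sigma: float) -> np.ndarray:
        frame = self.background.copy()
        cx = int(self.xs[t])
        self._stamp(frame, cx, self.cy, self.body_mask, self.body_tex)
        self._stamp(frame, cx + self.head_dx + int(self.head_offset[t]), self.cy,
                    self.patch_mask, self.patch_tex)
        if noise_sigma > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _SIDE_INDEX[self.side], int(t), 1]))
            frame = frame + rng.normal(0.0, noise_sigma, frame.shape)
        return np.clip(np.round(frame), 0, 255).astype(np.uint8)


class SyntheticSequence(FrameSequence):
    """Lazily rendered per-side frame sequence; bit-identical under its seed."""

    def __init__(self, spec: ScenarioSpec, side: str, source: str = "synthetic"):
        self.spec = spec
        self.side = side
        self.source = f"{source}:{side}"
        self.fps = 1.0
        self._model = _CageModel(spec, side)

    def __len__(self) -> int:
        return self.spec.duration_s

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.spec.frame_size[0] // 2, self.spec.frame_size[1]

    def iter_frames(self):
        for t in range(self.spec.duration_s):
            yield self._model.render(t, self.spec.seed, self.spec.noise_sigma)


def render_video(spec: ScenarioSpec, dataset: str = "synthetic"
                 ) -> tuple[SyntheticSequence, SyntheticSequence, GroundTruth]:
    """Render a scenario into one lazy frame sequence per cage side.

    Returns ``(left_seq, right_seq, ground_truth)``.  Rendering is fully
    deterministic in ``spec.seed``: the same spec yields bit-identical
    pixel arrays on every iteration and every call.
    """
    left = SyntheticSequence(spec, "left", source=dataset)
    right = SyntheticSequence(spec, "right", source=dataset)
    truth = GroundTruth(
        regimes={s: spec.regime_sequence(s) for s in ("left", "right")},
        clips=_regime_clips(spec, dataset),
    )
    return left, right, truth


def write_recording(spec: ScenarioSpec, out_dir: str | Path,
                    dataset: str = "synthetic") -> Path:
    """Write full two-cage frames as numbered PNGs plus a ground-truth manifest.

    Layout: ``<out_dir>/frames/frame_<t>.png`` and ``<out_dir>/ground_truth.csv``
    (columns dataset,side,start_frame,end_frame,duration_s,label where label
    is the true regime).
    """
    out = Path(out_dir)
    left, right, truth = render_video(spec, dataset=dataset)
    full = (np.hstack([lf, rf]) for lf, rf in zip(left, right))
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    width = max(6, len(str(spec.duration_s)))
    for t, frame in enumerate(full):
        iio.imwrite(frames_dir / f"frame_{t:0{width}d}.png", frame)
    write_manifest(truth.clips, out / "ground_truth.csv")
    return out


def sample_duration_dataset(n_clips: int, mixture: list[tuple[float, float, float]],
                            seed: int) -> np.ndarray:
    """Draw grooming-episode durations from a truncated-positive Gaussian mixture.

    ``mixture`` is a list of ``(mean_s, sd_s, weight)`` components whose
    weights sum to 1; draws <= 0 are rejected and redrawn within their
    component.  Modes near 16 s and 40 s reproduce the short/long duration
    structure pain shifts mass between.
    """
    if n_clips < 1:
        raise ValueError("n_clips must be >= 1")
    if not mixture:
        raise ValueError("mixture must have at least one component")
    means = np.array([m for m, _, _ in mixture], dtype=float)
    sds = np.array([s for _, s, _ in mixture], dtype=float)
    weights = np.array([w for _, _, w in mixture], dtype=float)
    if np.any(sds < 0):
        raise ValueError("component sd must be non-negative")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"mixture weights sum to {weights.sum():.6f}, expected 1")
    if np.any(means <= 0):
        raise ValueError("component means must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    comp = rng.choice(len(mixture), size=n_clips, p=weights)
    out = means[comp] + sds[comp] * rng.standard_normal(n_clips)
    bad = out <= 0
    while np.any(bad):
        idx = np.flatnonzero(bad)
        out[idx] = means[comp[idx]] + sds[comp[idx]] * rng.standard_normal(len(idx))
        bad = out <= 0
    return out


def make_classification_dataset(
    n_clips: int,
    seed: int,
    frame_size: tuple[int, int] = (64, 64),
    clip_len: int = 20,
    n_datasets: int = 6,
    noise_sigma: float = 2.0,
) -> list[dict]:
    """Build a balanced, labelled clip collection for classifier training.

    Alternating clips show grooming-like oscillation (positive class, label 1)
    and drastic locomotion (negative class, label 0), rendered at a reduced
    frame size for tractable training.  Clips are assigned round-robin to
    ``n_datasets`` synthetic datasets so the split protocols can be exercised.

    Returns a list of records ``{"seq", "label", "dataset", "clip"}`` where
    ``seq`` is an in-memory :class:`~groomkit.video_io.ArraySequence`.
    """
    records = []
    for i in range(n_clips):
        regime = "grooming" if i % 2 == 0 else "drastic"
        dataset = f"synth-{chr(ord('A') + (i % n_datasets))}"
        spec = ScenarioSpec(
            duration_s=clip_len,
            frame_size=frame_size,
            regimes={"left": [(regime, 0, clip_len)]},
            noise_sigma=noise_sigma,
            seed=int(np.random.SeedSequence([seed, 101, i]).generate_state(1)[0] % (2**31)),
        )
        left, _, _ = render_video(spec, dataset=dataset)
        frames = np.stack(list(left))
        clip = Clip(dataset, "left", 0, clip_len,
                    label="confirmed_grooming" if regime == "grooming"
                    else "confirmed_non_grooming")
        records.append(
            {
                "seq": ArraySequence(frames, side="left", source=clip.clip_id),
                "label": 1 if regime == "grooming" else 0,
                "dataset": dataset,
                "clip": clip,
                "clip_id": f"{dataset}:left:{i:04d}",
            }
        )
    return records
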