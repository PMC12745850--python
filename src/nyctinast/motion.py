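"""Per-frame motion quantification from time-lapse image sequences.

Motion between consecutive frames is the mean absolute difference of the
green channel (8-bit, 0-255).  The module also implements the artifact
exclusion rules used downstream: the frame at each lighting on/off switch
plus its neighbours (the camera flips to infrared mode and produces one huge
spurious difference), periodic video key frames, and everything from the
start of a watering event until 70 min after it ends (leaves close and
reopen on watering for reasons unrelated to the light cycle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .schedule import DEFAULT_CAPTURE_INTERVAL_S, LightingSchedule

__all__ = [
    "WATERING_RECOVERY_S",
    "MotionError",
    "WateringEvent",
    "FrameSeries",
    "frame_motion",
    "motion_series",
    "exclusion_mask",
    "gaussian_smooth",
    "load_frame_dir",
    "read_watering_log",
]

log = logging.getLogger(__name__)

#: Post-watering recovery period excluded from analysis: 70 min.
WATERING_RECOVERY_S = 70 * 60.0


class MotionError(ValueError):
    """Invalid motion computation input."""


@dataclass(frozen=True)
class WateringEvent:
    """A watering action from ``start_s`` to ``end_s`` (inclusive of spray)."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise MotionError("watering event ends before it starts")


@dataclass
class FrameSeries:
    """Per-frame motion values on the capture grid.

    ``motion`` has the same length as ``timestamps_s``; entry ``i`` is the
    change from frame ``i-1`` to frame ``i``, so the first entry is undefined
    (NaN) and flagged invalid whenever the series comes from differencing
    images.  This equal-length convention is used throughout the package.
    """

    timestamps_s: np.ndarray
    motion: np.ndarray
    valid: np.ndarray
    capture_interval_s: float = DEFAULT_CAPTURE_INTERVAL_S

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.timestamps_s) == len(self.motion) == len(self.valid)):
            raise MotionError("timestamps, motion and valid must be equal length")
        ok = self.valid & np.isfinite(self.motion)
        if np.any(self.motion[ok] < 0):
            raise MotionError("motion must be nonnegative where valid")

    def __len__(self) -> int:
        return len(self.timestamps_s)

    def mask(self, keep: np.ndarray) -> "FrameSeries":
        """New series whose validity is the conjunction with ``keep``."""
        return FrameSeries(
            self.timestamps_s, self.motion, self.valid & np.asarray(keep, bool),
            self.capture_interval_s,
        )

    def to_dataframe(self, schedule: LightingSchedule | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "timestamp_s": self.timestamps_s,
                "motion": self.motion,
                "valid": self.valid,
            }
        )
        if schedule is not None:
            labels = schedule.label_times(self.timestamps_s)
            df = pd.concat([df, labels[["cycle", "condition", "interval"]]], axis=1)
        return df

    def to_csv(self, path, schedule: LightingSchedule | None = None) -> None:
        self.to_dataframe(schedule).to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       capture_interval_s: float | None = None) -> "FrameSeries":
        ts = df["timestamp_s"].to_numpy(float)
        if capture_interval_s is None:
            capture_interval_s = float(np.median(np.diff(ts))) if len(ts) > 1 else DEFAULT_CAPTURE_INTERVAL_S
        valid = df["valid"].to_numpy(bool) if "valid" in df else np.isfinite(df["motion"].to_numpy(float))
        return cls(ts, df["motion"].to_numpy(float), valid, capture_interval_s)

    @classmethod
    def from_csv(cls, path, capture_interval_s: float | None = None) -> "FrameSeries":
        return cls.from_dataframe(pd.read_csv(path), capture_interval_s)


def _green(img: np.ndarray) -> np.ndarray:
    """Green channel of an RGB(A) image; grayscale is its own green channel."""
    a = np.asarray(img)
    if a.ndim == 3:
        return a[..., 1]
    if a.ndim == 2:
        return a
    raise MotionError(f"expected 2-D or 3-D image, got shape {a.shape}")


def frame_motion(prev_image: np.ndarray, cur_image: np.ndarray) -> float:
    """Mean absolute green-channel difference between two frames."""
    g0, g1 = _green(prev_image), _green(cur_image)
    if g0.shape != g1.shape:
        raise MotionError(f"image dimensions differ: {g0.shape} vs {g1.shape}")
    return float(np.mean(np.abs(g1.astype(np.float64) - g0.astype(np.float64))))


def motion_series(
    frame_source: Iterable[np.ndarray | None],
    schedule: LightingSchedule | None = None,
    frame_times: np.ndarray | None = None,
    capture_interval_s: float = DEFAULT_CAPTURE_INTERVAL_S,
) -> FrameSeries:
    """Frame-difference motion over an ordered frame sequence.

    ``frame_source`` yields images aligned to the schedule's capture grid; a
    ``None`` entry marks a missing/corrupt frame, which invalidates the two
    differences it touches (graceful degradation rather than an abort).
    """
    frames = list(frame_source)
    if frame_times is None:
        if schedule is None:
            raise MotionError("need a schedule or explicit frame_times")
        frame_times = schedule.frame_times(capture_interval_s)
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frames) != len(frame_times):
        raise MotionError(
            f"{len(frames)} frames do not match {len(frame_times)} grid times"
        )
    n = len(frames)
    motion = np.full(n, np.nan)
    valid = np.ones(n, dtype=bool)
    valid[0] = False
    for i in range(1, n):
        if frames[i - 1] is None or frames[i] is None:
            valid[i] = False
            if frames[i] is None:
                log.warning("missing frame at index %d; invalidating adjacent diffs", i)
            continue
        motion[i] = frame_motion(frames[i - 1], frames[i])
    return FrameSeries(frame_times, motion, valid, capture_interval_s)


def exclusion_mask(
    frame_times: np.ndarray,
    transition_times: np.ndarray | Sequence[float] = (),
    watering_events: Sequence[WateringEvent] = (),
    keyframe_period_frames: int | None = None,
    schedule: LightingSchedule | None = None,
) -> np.ndarray:
    """Boolean keep-mask over frames; ``False`` marks artifact frames.

    Excluded are (i) the frame at each lighting transition plus one frame
    before and after, (ii) every frame whose index is a multiple of the key
    frame period, and (iii) frames within ``[start, end + 70 min)`` of each
    watering event.  ``transition_times`` may be given directly or taken from
    ``schedule``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    keep = np.ones(n, dtype=bool)
    if schedule is not None:
        transition_times = schedule.transition_times()
    for t in np.asarray(transition_times, dtype=float):
        # the first frame at/after the switch carries the spurious diff
        k = int(np.searchsorted(frame_times, t, side="left"))
        if k >= n:
            continue
        keep[max(k - 1, 0) : min(k + 2, n)] = False
    if keyframe_period_frames is not None:
        if keyframe_period_frames <= 0:
            raise MotionError("key frame period must be a positive integer")
        keep[::keyframe_period_frames] = False
    for ev in watering_events:
        lo = ev.start_s
        hi = ev.end_s + WATERING_RECOVERY_S
        keep[(frame_times >= lo) & (frame_times < hi)] = False
    return keep


def gaussian_smooth(values: np.ndarray, window_frames: int = 50) -> np.ndarray:
    """Smooth with a normalized Gaussian kernel truncated to the window.

    Display-only helper (sigma = window/6, reflect-padded); statistics are
    always computed on the raw valid frames.
    """
    if window_frames < 1:
        raise MotionError("window must be >= 1 frame")
    values = np.asarray(values, dtype=float)
    radius = window_frames // 2
    if radius == 0:
        return values.copy()
    sigma = window_frames / 6.0
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    return ndimage.convolve1d(values, kernel, mode="reflect")


def load_frame_dir(path) -> list[np.ndarray]:
    """Read a directory of PNG/JPEG frames in zero-padded filename order."""
    import imageio.v3 as iio

    p = Path(path)
    files = sorted(
        f for f in p.iterdir() if f.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise MotionError(f"no PNG/JPEG frames found in {p}")
    return [np.asarray(iio.imread(f)) for f in files]


def read_watering_log(path) -> list[WateringEvent]:
    """Read a watering log CSV with ``start_s`` and ``end_s`` columns."""
    df = pd.read_csv(path)
    return [WateringEvent(float(r.start_s), float(r.end_s)) for r in df.itertuples()]
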