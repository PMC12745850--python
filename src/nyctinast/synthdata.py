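"""Synthetic motion series, rendered image sequences and injected artifacts.

The generator produces per-frame motion with the structure the analysis
assumes so every pipeline stage can be validated without recordings:

* a dark-hours baseline plus a boost while the lights are on;
* an exponentially decaying spike at every lights-on/off transition (leaves
  reorient sharply when illumination changes);
* an anticipatory pre-light effect that grows as ``a * log(cycle) + b``,
  coded symmetrically: +delta/2 on Light-day pre-light intervals, -delta/2 on
  Dark-day pre-light intervals, so the expected motion difference of cycle c
  is exactly ``delta(c)``.  The effect applies only when the cycle's day
  length lies in ``anticipation_band`` (default 12-24 h, the range in which
  the anticipation behaviour is expressed);
* Gaussian per-frame noise plus a per-cell Gaussian random effect that sets
  cycle-to-cycle scatter of cell means at the observed scale (~0.02 motion
  units) while keeping truncation at zero negligible.

``render_frames`` turns a motion series into a small synthetic image
sequence (swaying green leaflets on a light-state-dependent background) and
``inject_artifacts`` adds the three artifact types the exclusion rules
target: transition flashes, periodic key frames and watering spikes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .motion import FrameSeries, WateringEvent, WATERING_RECOVERY_S
from .schedule import (
    CONDITIONS,
    DEFAULT_CAPTURE_INTERVAL_S,
    INTERVALS,
    LightingSchedule,
)

__all__ = [
    "SimParams",
    "SceneParams",
    "GroundTruth",
    "simulate_motion",
    "render_frames",
    "inject_artifacts",
]


@dataclass
class SimParams:
    """Generative parameters of the synthetic motion series.

    Units are "motion units" — mean absolute green-level change per pixel,
    the same scale as the extracted series (dark baseline near 0.85).
    """

    baseline_dark: float = 0.85
    light_boost: float = 0.15
    spike_height: float = 2.0
    spike_decay_frames: int = 5
    a_true: float = 0.10
    b_true: float = -0.18
    anticipation_band: tuple[float, float] = (12.0, 24.0)
    noise_sd: float = 0.05
    cell_sd: float = 0.02
    seed: int = 0
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.baseline_dark <= 0:
            raise ValueError("baseline_dark must be positive")
        if self.noise_sd < 0 or self.cell_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.spike_decay_frames < 1:
            raise ValueError("spike_decay_frames must be >= 1")

    def delta(self, cycle: int, day_length_h: float) -> float:
        """Anticipation effect delta(c) = a*log(c) + b, zero outside the band."""
        lo, hi = self.anticipation_band
        if not (lo <= day_length_h <= hi):
            return 0.0
        return self.a_true * math.log(cycle) / math.log(self.log_base) + self.b_true


@dataclass
class SceneParams:
    """Geometry of the rendered synthetic plant scene."""

    width: int = 320
    height: int = 180
    n_leaflets: int = 12
    leaflet_length_px: float = 36.0
    leaflet_width_px: int = 3
    green_level: int = 200
    background_dark: int = 12
    background_light: int = 90
    sway_gain_deg: float = 3.0  # jitter amplitude in degrees per motion unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sway_gain_deg <= 0:
            raise ValueError("sway gain must be positive")
        if self.leaflet_length_px * 2 > min(self.width, self.height) * 2:
            raise ValueError("leaflets must fit inside the image")


@dataclass
class GroundTruth:
    """Analytic expectations stored alongside a simulated series."""

    cell_expectations: pd.DataFrame  # cycle, condition, interval, expected_mean
    expected_differences: pd.Series  # delta(c) per cycle
    params: SimParams

    def expected_cell(self, cycle: int, condition: str, interval: str) -> float:
        d = self.cell_expectations
        sel = d[
            (d["cycle"] == cycle) & (d["condition"] == condition) & (d["interval"] == interval)
        ]
        return float(sel["expected_mean"].iloc[0])

    def to_json(self, path=None) -> str:
        payload = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.params).items()
            },
            "expected_differences": {int(k): v for k, v in self.expected_differences.items()},
            "cell_expectations": self.cell_expectations.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _expected_motion(
    params: SimParams, schedule: LightingSchedule, ts: np.ndarray, labels: pd.DataFrame
) -> np.ndarray:
    """Deterministic per-frame expectation (no noise, no cell effects)."""
    n = len(ts)
    mu = np.full(n, params.baseline_dark)
    mu[labels["light_on"].to_numpy()] += params.light_boost

    # transition spikes, exponential decay in frames
    decay = params.spike_decay_frames
    tail = int(math.ceil(8 * decay))
    for t in schedule.transition_times():
        k = int(np.searchsorted(ts, t, side="left"))
        if k >= n:
            continue
        idx = np.arange(k, min(k + tail, n))
        mu[idx] += params.spike_height * np.exp(-(idx - k) / decay)

    # anticipation: +delta/2 pre-light on Light days, -delta/2 on Dark days
    cyc = labels["cycle"].to_numpy()
    cond = labels["condition"].to_numpy()
    pre = labels["interval"].to_numpy() == "pre-light"
    for c in range(1, schedule.n_cycles + 1):
        d = params.delta(c, schedule.day_length_of_cycle(c))
        if d == 0.0:
            continue
        sel = pre & (cyc == c)
        sign = np.where(cond[sel] == "Dark", -1.0, 1.0)
        mu[sel] += sign * d / 2.0
    return mu


def simulate_motion(
    params: SimParams,
    schedule: LightingSchedule,
    capture_interval_s: float = DEFAULT_CAPTURE_INTERVAL_S,
) -> tuple[FrameSeries, GroundTruth]:
    """Simulate a per-frame motion series and its analytic ground truth.

    Realized motion = expectation + per-cell random effect + per-frame
    Gaussian noise, truncated at zero.  All frames of a directly simulated
    series are valid (there is no differencing step to lose the first frame
    to).  Ground-truth cell expectations are exact frame averages of the
    deterministic expectation, so a noise-free run reproduces them to
    machine precision.
    """
    ts = schedule.frame_times(capture_interval_s)
    labels = schedule.label_times(ts)
    mu = _expected_motion(params, schedule, ts, labels)

    rng = np.random.default_rng(params.seed)
    motion = mu.copy()
    if params.cell_sd > 0:
        cells = labels[["cycle", "condition", "interval"]]
        codes, _ = pd.factorize(
            cells["cycle"].astype(str) + "|" + cells["condition"] + "|" + cells["interval"]
        )
        offsets = rng.normal(0.0, params.cell_sd, size=codes.max() + 1)
        motion = motion + offsets[codes]
    if params.noise_sd > 0:
        motion = motion + rng.normal(0.0, params.noise_sd, size=len(ts))
    motion = np.maximum(motion, 0.0)

    series = FrameSeries(ts, motion, np.ones(len(ts), bool), capture_interval_s)

    gt_cells = (
        labels.assign(expected_mean=mu)
        .groupby(["cycle", "condition", "interval"], sort=True)["expected_mean"]
        .mean()
        .reset_index()
    )
    deltas = pd.Series(
        {
            c: params.delta(c, schedule.day_length_of_cycle(c))
            for c in range(1, schedule.n_cycles + 1)
        },
        name="expected_difference",
    )
    return series, GroundTruth(gt_cells, deltas, params)


def render_frames(
    series: FrameSeries,
    scene: SceneParams,
    schedule: LightingSchedule,
    out_dir=None,
) -> list[np.ndarray]:
    """Render a synthetic leaflet scene realizing a motion series.

    Each frame draws ``n_leaflets`` green line segments whose angles are
    jittered with amplitude proportional to the frame's motion value; the
    background green level follows the light state.  Deterministic for a
    given scene seed.  When ``out_dir`` is given, frames are also written as
    zero-padded PNGs.
    """
    from PIL import Image, ImageDraw

    ts = series.timestamps_s
    labels = schedule.label_times(ts)
    light_on = labels["light_on"].to_numpy()

    rng = np.random.default_rng(scene.seed)
    # fixed anchors and rest angles for the whole sequence
    xs = rng.uniform(scene.leaflet_length_px, scene.width - scene.leaflet_length_px, scene.n_leaflets)
    ys = rng.uniform(scene.leaflet_length_px, scene.height - scene.leaflet_length_px, scene.n_leaflets)
    base_angles = rng.uniform(0, 2 * np.pi, scene.n_leaflets)
    jitter = rng.uniform(-1.0, 1.0, size=(len(ts), scene.n_leaflets))

    motion = np.nan_to_num(series.motion, nan=0.0)
    frames: list[np.ndarray] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i in range(len(ts)):
        bg = scene.background_light if light_on[i] else scene.background_dark
        img = Image.new("RGB", (scene.width, scene.height), (0, bg, 0))
        draw = ImageDraw.Draw(img)
        amp = math.radians(scene.sway_gain_deg) * motion[i]
        angles = base_angles + amp * jitter[i]
        for j in range(scene.n_leaflets):
            x1 = xs[j] + scene.leaflet_length_px * math.cos(angles[j])
            y1 = ys[j] + scene.leaflet_length_px * math.sin(angles[j])
            draw.line(
                [(xs[j], ys[j]), (x1, y1)],
                fill=(0, scene.green_level, 0),
                width=scene.leaflet_width_px,
            )
        arr = np.asarray(img)
        frames.append(arr)
        if out is not None:
            img.save(out / f"frame_{i:06d}.png")
    return frames


def inject_artifacts(
    series: FrameSeries,
    schedule: LightingSchedule,
    watering_events: Sequence[WateringEvent] = (),
    keyframe_period: int | None = None,
    flash_height: float = 60.0,
    watering_height: float = 2.0,
    watering_decay_s: float = 600.0,
) -> FrameSeries:
    """Return a corrupted copy of a motion series.

    Adds a flash value at every lighting-transition frame, a spike at every
    ``keyframe_period``-th frame, and elevated motion through each watering
    window with an exponential decay afterwards.  The decay is truncated at
    the 70-min post-watering boundary — the recovery period the exclusion
    window is designed to cover — so masking restores the clean statistics
    exactly.  Validity flags are left untouched: corruption, not masking.
    """
    ts = series.timestamps_s
    motion = series.motion.copy()
    n = len(ts)
    for t in schedule.transition_times():
        k = int(np.searchsorted(ts, t, side="left"))
        if k < n:
            motion[k] += flash_height
    if keyframe_period is not None:
        if keyframe_period <= 0:
            raise ValueError("keyframe_period must be a positive integer")
        motion[::keyframe_period] += flash_height
    for ev in watering_events:
        during = (ts >= ev.start_s) & (ts < ev.end_s)
        motion[during] += watering_height
        after = (ts >= ev.end_s) & (ts < ev.end_s + WATERING_RECOVERY_S)
        motion[after] += watering_height * np.exp(-(ts[after] - ev.end_s) / watering_decay_s)
    return FrameSeries(ts, motion, series.valid.copy(), series.capture_interval_s)
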