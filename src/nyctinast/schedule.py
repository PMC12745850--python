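"""Light/dark schedule construction for light-light-dark (L1-L2-D) experiments.

A *cycle* is one Light1-Light2-Dark repetition.  Each of the three "days" in a
cycle has the same length ``N`` hours.  On a Light day the lights follow the
N/4 (dark) - N/2 (light) - N/4 (dark) pattern; on the Dark day the lights stay
off for the whole ``N`` hours.  The same clock partition into *pre-light*
[0, N/4), *light-on* [N/4, 3N/4) and *post-light* [3N/4, N) intervals is
applied to Dark days even though the lights never turn on there.

Three phase presets are provided:

* phase 1 - constant 24-h days (72-h cycle, lights on 6 h after local midnight
  for 12 h);
* phase 2 - constant 20-h days (60-h cycle, 5 h off / 10 h on / 5 h off);
* phase 3 - a day length drawn at random at the start of every cycle from a
  configurable set (default: even hours from 10 to 32).

All times are seconds from the phase origin; every interval is half-open
``[start, end)``, so a timestamp equal to a boundary belongs to the later
segment.  Cycle indices are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "INTERVALS",
    "DEFAULT_DAY_LENGTH_SET",
    "ScheduleError",
    "Segment",
    "FrameLabel",
    "LightingSchedule",
    "build_cycle",
    "build_phase",
    "longest_dark_run",
    "label_time",
    "frame_times",
]

#: Day conditions within one cycle, in order.
CONDITIONS = ("Light1", "Light2", "Dark")

#: Time-of-day intervals within one day, in order.
INTERVALS = ("pre-light", "light-on", "post-light")

#: Phase-3 default day-length support: even hours from 10 to 32 inclusive.
DEFAULT_DAY_LENGTH_SET = tuple(range(10, 33, 2))

#: Default capture cadence of the time-lapse camera, seconds.
DEFAULT_CAPTURE_INTERVAL_S = 20.0


class ScheduleError(ValueError):
    """Invalid schedule construction or query."""


@dataclass(frozen=True)
class Segment:
    """One contiguous run of constant lighting state.

    ``interval`` is ``None`` for the single whole-day Dark segment; the
    time-of-day interval of any timestamp is always recoverable through
    :func:`label_time`, which applies the clock partition arithmetically.
    """

    start_s: float
    end_s: float
    light_state: str  # "on" | "off"
    cycle_index: int
    condition: str  # "Light1" | "Light2" | "Dark"
    interval: str | None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FrameLabel:
    """Label of a single time point: cycle, day condition, interval, state."""

    cycle_index: int
    condition: str
    interval: str
    light_state: str


def build_cycle(
    day_length_h: float, cycle_index: int = 1, t0_s: float = 0.0
) -> list[Segment]:
    """Build the 7 segments of one Light1-Light2-Dark cycle.

    Each Light day contributes dark N/4, light N/2, dark N/4; the Dark day is
    a single all-dark segment of length N.  The cycle spans exactly
    ``3 * day_length_h`` hours from ``t0_s``.
    """
    if not day_length_h > 0:
        raise ScheduleError(f"day length must be positive, got {day_length_h}")
    if cycle_index < 1:
        raise ScheduleError("cycle indices are 1-based")
    n_s = day_length_h * 3600.0
    segs: list[Segment] = []
    t = t0_s
    for condition in ("Light1", "Light2"):
        day0 = t
        segs.append(Segment(day0, day0 + n_s / 4, "off", cycle_index, condition, "pre-light"))
        segs.append(Segment(day0 + n_s / 4, day0 + 3 * n_s / 4, "on", cycle_index, condition, "light-on"))
        segs.append(Segment(day0 + 3 * n_s / 4, day0 + n_s, "off", cycle_index, condition, "post-light"))
        t = day0 + n_s
    segs.append(Segment(t, t + n_s, "off", cycle_index, "Dark", None))
    return segs


@dataclass
class LightingSchedule:
    """An ordered, contiguous sequence of lighting segments over whole cycles."""

    segments: list[Segment]
    phase_id: int | str = 0
    day_lengths_h: list[float] = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScheduleError("schedule has no segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s != a.end_s:
                raise ScheduleError("segments must be contiguous and sorted")
        if not self.day_lengths_h:
            # recover per-cycle day lengths from the segment spans
            spans: dict[int, float] = {}
            for s in self.segments:
                spans[s.cycle_index] = spans.get(s.cycle_index, 0.0) + s.duration_s
            self.day_lengths_h = [spans[c] / 3.0 / 3600.0 for c in sorted(spans)]
        starts = np.cumsum([0.0] + [3 * n * 3600.0 for n in self.day_lengths_h])
        self._cycle_starts_s = starts + self.segments[0].start_s

    # -- basic geometry ----------------------------------------------------

    @property
    def t0_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def span_s(self) -> float:
        return self.end_s - self.t0_s

    @property
    def n_cycles(self) -> int:
        return len(self.day_lengths_h)

    def day_length_of_cycle(self, cycle_index: int) -> float:
        return self.day_lengths_h[cycle_index - 1]

    # -- queries -----------------------------------------------------------

    def label_times(self, t_s: np.ndarray) -> pd.DataFrame:
        """Vectorised :func:`label_time` over an array of timestamps.

        Returns a DataFrame with columns ``cycle``, ``condition``,
        ``interval``, ``light_on`` and ``day_length_h``.
        """
        t = np.asarray(t_s, dtype=float)
        if t.size and (t.min() < self.t0_s or t.max() >= self.end_s):
            raise ScheduleError("timestamp outside schedule span")
        starts = self._cycle_starts_s
        k = np.searchsorted(starts, t, side="right") - 1
        k = np.clip(k, 0, self.n_cycles - 1)
        n_s = np.asarray(self.day_lengths_h, dtype=float)[k] * 3600.0
        local = t - starts[k]
        day_idx = np.minimum((local // n_s).astype(int), 2)
        u = local - day_idx * n_s
        # exact boundary comparisons: 4u vs N and 4u vs 3N avoid division
        interval_idx = np.where(4 * u < n_s, 0, np.where(4 * u < 3 * n_s, 1, 2))
        light_on = (day_idx < 2) & (interval_idx == 1)
        return pd.DataFrame(
            {
                "cycle": k + 1,
                "condition": np.asarray(CONDITIONS, dtype=object)[day_idx],
                "interval": np.asarray(INTERVALS, dtype=object)[interval_idx],
                "light_on": light_on,
                "day_length_h": n_s / 3600.0,
            }
        )

    def label_time(self, t_s: float) -> FrameLabel:
        row = self.label_times(np.asarray([t_s])).iloc[0]
        return FrameLabel(
            cycle_index=int(row["cycle"]),
            condition=str(row["condition"]),
            interval=str(row["interval"]),
            light_state="on" if bool(row["light_on"]) else "off",
        )

    def frame_times(
        self, capture_interval_s: float = DEFAULT_CAPTURE_INTERVAL_S
    ) -> np.ndarray:
        """Capture timestamps t0, t0+d, ... strictly inside the span.

        The count is ``floor(span / d)``: a 24-h span at the 20-s default
        cadence yields 4320 frames.
        """
        if not capture_interval_s > 0:
            raise ScheduleError("capture interval must be positive")
        n = int(np.floor(self.span_s / capture_interval_s))
        return self.t0_s + np.arange(n) * float(capture_interval_s)

    def transition_times(self) -> np.ndarray:
        """Times at which the lights switch on or off, in order."""
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.light_state != b.light_state:
                out.append(b.start_s)
        return np.asarray(out, dtype=float)

    def longest_dark_run_h(self) -> float:
        """Longest contiguous lights-off duration, in hours.

        Off-runs may span cycle boundaries (post-light + Dark day + next
        pre-light); for a constant-N schedule with a following cycle this is
        1.5*N h.
        """
        best = 0.0
        run = 0.0
        for s in self.segments:
            if s.light_state == "off":
                run += s.duration_s
                best = max(best, run)
            else:
                run = 0.0
        return best / 3600.0

    # -- serialization -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start_s": s.start_s,
                    "end_s": s.end_s,
                    "state": s.light_state,
                    "cycle": s.cycle_index,
                    "condition": s.condition,
                    "interval": "" if s.interval is None else s.interval,
                }
                for s in self.segments
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, phase_id: int | str = 0, rng_seed: int | None = None
    ) -> "LightingSchedule":
        segs = [
            Segment(
                float(r.start_s),
                float(r.end_s),
                str(r.state),
                int(r.cycle),
                str(r.condition),
                None if (pd.isna(r.interval) or r.interval == "") else str(r.interval),
            )
            for r in df.itertuples()
        ]
        return cls(segs, phase_id=phase_id, rng_seed=rng_seed)

    @classmethod
    def from_csv(cls, path, phase_id: int | str = 0) -> "LightingSchedule":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False), phase_id=phase_id)

    def to_json(self, path=None) -> str:
        payload = {
            "phase_id": self.phase_id,
            "rng_seed": self.rng_seed,
            "day_lengths_h": list(self.day_lengths_h),
            "segments": [dataclasses.asdict(s) for s in self.segments],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LightingSchedule":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        segs = [Segment(**d) for d in payload["segments"]]
        return cls(
            segs,
            phase_id=payload.get("phase_id", 0),
            day_lengths_h=list(payload.get("day_lengths_h", [])),
            rng_seed=payload.get("rng_seed"),
        )


# -- module-level functional surface --------------------------------------


def build_phase(
    phase_id: int | str,
    n_cycles: int,
    seed: int | None = None,
    day_lengths: Sequence[float] | None = None,
    day_length_set: Sequence[float] = DEFAULT_DAY_LENGTH_SET,
    t0_s: float = 0.0,
) -> LightingSchedule:
    """Build a whole-phase schedule.

    Phase 1 uses 24-h days (72-h cycles), phase 2 uses 20-h days (60-h
    cycles), phase 3 draws a day length per cycle uniformly from
    ``day_length_set`` (requires ``seed``).  An explicit ``day_lengths``
    sequence overrides the policy and must have one entry per cycle.
    """
    if n_cycles < 1:
        raise ScheduleError("n_cycles must be >= 1")
    if day_lengths is not None:
        if len(day_lengths) != n_cycles:
            raise ScheduleError("day_lengths must have one entry per cycle")
        lengths = [float(n) for n in day_lengths]
    elif phase_id in (1, "1"):
        lengths = [24.0] * n_cycles
    elif phase_id in (2, "2"):
        lengths = [20.0] * n_cycles
    elif phase_id in (3, "3"):
        if seed is None:
            raise ScheduleError("phase 3 requires a seed for the day-length draws")
        rng = np.random.default_rng(seed)
        lengths = [float(x) for x in rng.choice(np.asarray(day_length_set, dtype=float), size=n_cycles)]
    else:
        raise ScheduleError(f"unknown phase_id {phase_id!r}")

    segs: list[Segment] = []
    t = float(t0_s)
    for c, n in enumerate(lengths, start=1):
        segs.extend(build_cycle(n, cycle_index=c, t0_s=t))
        t += 3 * n * 3600.0
    return LightingSchedule(segs, phase_id=phase_id, day_lengths_h=lengths, rng_seed=seed)


def longest_dark_run(schedule: LightingSchedule) -> float:
    """Longest contiguous lights-off run of the schedule, hours."""
    return schedule.longest_dark_run_h()


def label_time(t_s: float, schedule: LightingSchedule) -> FrameLabel:
    """Label a time point with (cycle, condition, interval, light state)."""
    return schedule.label_time(t_s)


def frame_times(
    schedule: LightingSchedule, capture_interval_s: float = DEFAULT_CAPTURE_INTERVAL_S
) -> np.ndarray:
    """Capture timestamps of the schedule at the given cadence."""
    return schedule.frame_times(capture_interval_s)
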