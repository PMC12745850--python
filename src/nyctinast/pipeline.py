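"""End-to-end run orchestration: schedule -> (simulate|extract) -> analyze.

A run is described by a single declarative YAML config (see
:class:`RunConfig`); all randomness flows from one root seed through named
substreams, so re-running an identical synthetic config reproduces every
numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .motion import (
    FrameSeries,
    MotionError,
    exclusion_mask,
    load_frame_dir,
    motion_series,
    read_watering_log,
)
from .schedule import LightingSchedule, ScheduleError, build_phase
from .stats import (
    PRE_LIGHT,
    StatsError,
    cell_means,
    fit_log_curve,
    rm_anova,
    simple_effects,
    stratify_by_day_length,
)
from .synthdata import SimParams, inject_artifacts, simulate_motion

__all__ = ["ConfigError", "DataError", "RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)

INPUT_MODES = ("synthetic", "frames", "series")


class ConfigError(ValueError):
    """The run configuration is invalid (exit code 2)."""


class DataError(RuntimeError):
    """Input data could not be read or processed (exit code 3)."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str  # synthetic | frames | series
    out_dir: str
    seed: int | None = None
    phase: dict = field(default_factory=lambda: {"id": 1, "n_cycles": 5})
    frames_dir: str | None = None
    series_csv: str | None = None
    schedule_csv: str | None = None
    capture_interval_s: float = 20.0
    sim: dict = field(default_factory=dict)
    exclusion: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                d = yaml.safe_load(fh)
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def validate(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ConfigError(
                f"input mode must be one of {INPUT_MODES}, got {self.mode!r}"
            )
        if self.mode == "synthetic" and self.seed is None:
            raise ConfigError("synthetic mode requires a seed")
        if self.mode == "frames" and not self.frames_dir:
            raise ConfigError("frames mode requires frames_dir")
        if self.mode == "series" and not self.series_csv:
            raise ConfigError("series mode requires series_csv")
        sources = [self.frames_dir, self.series_csv]
        if sum(s is not None for s in sources) > 1:
            raise ConfigError("exactly one input source may be given")
        if not self.out_dir:
            raise ConfigError("out_dir is required")
        if "id" not in self.phase:
            raise ConfigError("phase.id is required")

    def canonical_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        text = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunReport:
    """In-memory results of a pipeline run plus the written file manifest."""

    config: RunConfig
    schedule: LightingSchedule
    series: FrameSeries
    cells: Any
    differences: pd.Series
    curve_fit: Any
    anova: Any
    pre_light_effects: Any
    stratification: dict | None
    manifest: dict


def _substreams(seed: int) -> tuple[int, int]:
    """Derive (schedule, simulation) child seeds below 2**31 from one root."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2)
    return tuple(int(k.generate_state(1)[0] % (2**31)) for k in kids)


def _log_base(analysis: dict) -> float:
    b = analysis.get("log_base", "e")
    if b in ("e", None):
        return math.e
    return float(b)


def run_pipeline(config: RunConfig, make_figures: bool = True) -> RunReport:
    """Execute one full run and write the report bundle to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save(name: str) -> Path:
        written.append(name)
        return out / name

    # -- schedule ----------------------------------------------------------
    sched_seed, sim_seed = _substreams(config.seed if config.seed is not None else 0)
    try:
        if config.schedule_csv:
            schedule = LightingSchedule.from_csv(
                config.schedule_csv, phase_id=config.phase.get("id", 0)
            )
        else:
            schedule = build_phase(
                config.phase["id"],
                n_cycles=int(config.phase.get("n_cycles", 5)),
                seed=sched_seed,
                day_lengths=config.phase.get("day_lengths"),
                day_length_set=tuple(
                    config.phase.get("day_length_set", range(10, 33, 2))
                ),
            )
    except ScheduleError as exc:
        raise ConfigError(f"schedule stage: {exc}") from exc
    schedule.to_csv(save("schedule.csv"))
    schedule.to_json(save("schedule.json"))

    # -- motion series -----------------------------------------------------
    try:
        ground_truth = None
        if config.mode == "synthetic":
            params = SimParams(**{**config.sim, "seed": sim_seed})
            series, ground_truth = simulate_motion(
                params, schedule, config.capture_interval_s
            )
            if config.exclusion.get("inject_artifacts"):
                series = inject_artifacts(
                    series,
                    schedule,
                    keyframe_period=config.exclusion.get("keyframe_period"),
                )
        elif config.mode == "frames":
            frames = load_frame_dir(config.frames_dir)
            series = motion_series(
                frames, schedule, capture_interval_s=config.capture_interval_s
            )
        else:
            series = FrameSeries.from_csv(config.series_csv)
    except (MotionError, OSError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise DataError(f"motion stage: {exc}") from exc

    # -- artifact exclusion --------------------------------------------------
    watering = []
    if config.exclusion.get("watering_csv"):
        watering = read_watering_log(config.exclusion["watering_csv"])
    keep = exclusion_mask(
        series.timestamps_s,
        watering_events=watering,
        keyframe_period_frames=config.exclusion.get("keyframe_period"),
        schedule=schedule,
    )
    series = series.mask(keep)
    series.to_csv(save("series.csv"), schedule=schedule)
    if ground_truth is not None:
        ground_truth.to_json(save("ground_truth.json"))

    # -- statistics ----------------------------------------------------------
    try:
        cells = cell_means(series, schedule)
        cells.to_csv(save("cells.csv"))
        differences = cells.motion_differences()
        differences.rename_axis("cycle").to_csv(save("differences.csv"))

        base = _log_base(config.analysis)
        curve = None
        if len(differences.dropna()) >= 2:
            curve = fit_log_curve(differences, log_base=base)
            save("learning_curve.json").write_text(json.dumps(curve.to_dict(), indent=1))

        variable_n = len(set(schedule.day_lengths_h)) > 1
        covariates = tuple(
            config.analysis.get(
                "covariates", ("cycle", "day_length") if variable_n else ("cycle",)
            )
        )
        anova = pre = None
        if schedule.n_cycles >= 3 + len(covariates):
            anova = rm_anova(cells, covariates=covariates)
            anova.to_csv(save("anova.csv"))
            pre = simple_effects(cells, PRE_LIGHT, covariates=covariates)
            pre.to_csv(save("simple_effects_prelight.csv"))

        strat = None
        if variable_n:
            band = tuple(config.analysis.get("band", (12.0, 24.0)))
            strat = stratify_by_day_length(
                differences, cells.day_lengths(), band=band, log_base=base
            )
            payload = {
                k: {
                    "cycles": list(v.cycles),
                    "n_cycles": v.n_cycles,
                    "mean_difference": v.mean_difference,
                    "fit": v.fit.to_dict() if v.fit else None,
                }
                for k, v in strat.items()
            }
            save("stratification.json").write_text(json.dumps(payload, indent=1))
    except StatsError as exc:
        raise DataError(f"stats stage: {exc}") from exc

    # -- figures ---------------------------------------------------------------
    if make_figures:
        from . import plots

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        plots.plot_motion_trace(series, schedule, path=figdir / "motion_trace.png")
        plots.plot_cell_means(cells, path=figdir / "cell_means.png")
        if curve is not None:
            plots.plot_learning_curve(
                differences.dropna(), curve, path=figdir / "learning_curve.png"
            )
        if variable_n:
            plots.plot_difference_by_day_length(
                differences,
                cells.day_lengths(),
                band=tuple(config.analysis.get("band", (12.0, 24.0))),
                path=figdir / "difference_by_day_length.png",
            )
        written.extend(f"figures/{p.name}" for p in sorted(figdir.iterdir()))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_cycles": schedule.n_cycles,
        "n_frames": len(series),
        "n_valid_frames": int(series.valid.sum()),
        "files": sorted(written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunReport(
        config=config,
        schedule=schedule,
        series=series,
        cells=cells,
        differences=differences,
        curve_fit=curve,
        anova=anova,
        pre_light_effects=pre,
        stratification=strat,
        manifest=manifest,
    )
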