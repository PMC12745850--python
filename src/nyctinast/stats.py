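"""Anticipation statistics for light-light-dark motion experiments.

The analysis pipeline is: bin per-frame motion into (cycle x day condition x
time-of-day) cell means; form the per-cycle anticipation statistic

    motion difference = (pre-light Light1 + pre-light Light2) / 2 - pre-light Dark,

fit the learning curve ``difference = a * log(cycle) + b``; and summarise the
full design with a repeated-measures ANOVA (within factors: day condition and
time-of-day, each 3 levels; observational unit: the cycle; cycle number and,
for variable day lengths, day length as centered continuous covariates).

The ANOVA uses the balanced within-subject partition.  Within each
within-factor stratum the cycle-level contrast scores are regressed on the
centered covariates; Type-III sums of squares fall out of the
extra-sum-of-squares comparison, and the residual degrees of freedom are
``df_factor * (n - 1 - p)`` for ``n`` cycles and ``p`` covariates.  No
established Python package fits this within-factor-by-covariate design, so
the partition is implemented directly; it reduces to the classical two-way
repeated-measures ANOVA when no covariates are given.

Model classes follow the Model/Results convention: construct a model from a
:class:`CellTable`, call ``fit()`` and inspect the Results object
(``summary()``, tidy DataFrame, effect sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motion import FrameSeries
from .schedule import CONDITIONS, INTERVALS, LightingSchedule

__all__ = [
    "StatsError",
    "CellTable",
    "cell_means",
    "motion_difference",
    "LearningCurve",
    "LearningCurveResults",
    "fit_log_curve",
    "partial_eta_sq",
    "error_df",
    "RepeatedMeasuresAnova",
    "AnovaResults",
    "rm_anova",
    "simple_effects",
    "stratify_by_day_length",
    "StratumSummary",
]

PRE_LIGHT, LIGHT_ON, POST_LIGHT = INTERVALS
LIGHT1, LIGHT2, DARK = CONDITIONS


class StatsError(ValueError):
    """Invalid statistical computation."""


# ---------------------------------------------------------------------------
# Cell table
# ---------------------------------------------------------------------------


class CellTable:
    """Mean motion per (cycle x day condition x time-of-day) cell.

    Wraps a tidy DataFrame with columns ``cycle``, ``condition``,
    ``interval``, ``mean``, ``n_frames`` and ``day_length_h``.  Cells with no
    valid frames carry ``mean = NaN`` and ``n_frames = 0`` (missing, never
    silently zero).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"cycle", "condition", "interval", "mean", "n_frames"}
        missing = required - set(data.columns)
        if missing:
            raise StatsError(f"cell table missing columns: {sorted(missing)}")
        if "day_length_h" not in data.columns:
            data = data.assign(day_length_h=np.nan)
        self.data = data.sort_values(["cycle", "condition", "interval"]).reset_index(drop=True)

    @property
    def cycles(self) -> np.ndarray:
        return np.unique(self.data["cycle"].to_numpy())

    def cell(self, cycle: int, condition: str, interval: str) -> float:
        sel = self.data[
            (self.data["cycle"] == cycle)
            & (self.data["condition"] == condition)
            & (self.data["interval"] == interval)
        ]
        if sel.empty:
            return float("nan")
        return float(sel["mean"].iloc[0])

    def day_length(self, cycle: int) -> float:
        sel = self.data[self.data["cycle"] == cycle]
        return float(sel["day_length_h"].iloc[0]) if not sel.empty else float("nan")

    def day_lengths(self) -> pd.Series:
        return self.data.groupby("cycle")["day_length_h"].first()

    def weighted_mean(self) -> float:
        """Frame-count-weighted grand mean; equals the global valid-frame mean."""
        d = self.data[self.data["n_frames"] > 0]
        return float(np.average(d["mean"], weights=d["n_frames"]))

    def pivot(self, interval: str | None = None) -> pd.DataFrame:
        d = self.data if interval is None else self.data[self.data["interval"] == interval]
        return d.pivot_table(index="cycle", columns=["condition", "interval"], values="mean")

    def condition_interval_summary(self) -> pd.DataFrame:
        """Across-cycle mean and SEM per (condition, interval) cell."""
        g = self.data.groupby(["condition", "interval"])["mean"]
        out = g.agg(N="count", Mean="mean", SEM=lambda x: x.std(ddof=1) / math.sqrt(len(x)))
        return out.reset_index()

    def motion_differences(self) -> pd.Series:
        """Per-cycle anticipation statistic (see :func:`motion_difference`)."""
        return pd.Series(
            {int(c): motion_difference(self, int(c)) for c in self.cycles},
            name="motion_difference",
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellTable":
        return cls(pd.read_csv(path))


def cell_means(series: FrameSeries, schedule: LightingSchedule) -> CellTable:
    """Bin valid frames into per-cell arithmetic means.

    Only frames with ``valid == True`` enter; a cell left without valid
    frames is flagged missing.  The full cycle x condition x interval grid is
    always present in the output.
    """
    labels = schedule.label_times(series.timestamps_s)
    df = labels.assign(motion=series.motion, valid=series.valid)
    dfv = df[df["valid"] & np.isfinite(df["motion"])]
    agg = (
        dfv.groupby(["cycle", "condition", "interval"], sort=True)["motion"]
        .agg(["mean", "count"])
        .rename(columns={"count": "n_frames"})
    )
    cycles = np.arange(1, schedule.n_cycles + 1)
    grid = pd.MultiIndex.from_product(
        [cycles, CONDITIONS, INTERVALS], names=["cycle", "condition", "interval"]
    )
    agg = agg.reindex(grid)
    agg["n_frames"] = agg["n_frames"].fillna(0).astype(int)
    out = agg.reset_index()
    out["day_length_h"] = [schedule.day_length_of_cycle(int(c)) for c in out["cycle"]]
    return CellTable(out)


def motion_difference(table: CellTable, cycle_index: int) -> float:
    """(pre-light L1 + pre-light L2)/2 - pre-light Dark for one cycle.

    Positive values mean more pre-light movement on days when light is
    coming than on the dark day.  Missing cells propagate to NaN.
    """
    l1 = table.cell(cycle_index, LIGHT1, PRE_LIGHT)
    l2 = table.cell(cycle_index, LIGHT2, PRE_LIGHT)
    d = table.cell(cycle_index, DARK, PRE_LIGHT)
    return (l1 + l2) / 2.0 - d


# ---------------------------------------------------------------------------
# Learning curve
# ---------------------------------------------------------------------------


@dataclass
class LearningCurveResults:
    """Fitted logarithmic learning curve ``a * log(cycle) + b``."""

    slope: float
    intercept: float
    rsquared: float
    n_cycles: int
    log_base: float

    @property
    def params(self) -> tuple[float, float]:
        return (self.slope, self.intercept)

    def predict(self, cycles) -> np.ndarray:
        c = np.asarray(cycles, dtype=float)
        return self.slope * np.log(c) / np.log(self.log_base) + self.intercept

    def summary(self) -> str:
        base = "e" if math.isclose(self.log_base, math.e) else f"{self.log_base:g}"
        r2 = "NA" if np.isnan(self.rsquared) else f"{self.rsquared:.3f}"
        return (
            "Logarithmic learning curve\n"
            f"  difference = {self.slope:.4f} * log_{base}(cycle) {self.intercept:+.4f}\n"
            f"  r^2 = {r2}   cycles = {self.n_cycles}"
        )

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": None if np.isnan(self.rsquared) else self.rsquared,
            "n_cycles": self.n_cycles,
            "log_base": self.log_base,
        }


class LearningCurve:
    """Least-squares model for a response against log(cycle number).

    Parameters
    ----------
    differences : Series indexed by 1-based cycle, or array-like
        The per-cycle response (typically the motion difference).
    cycles : array-like, optional
        Cycle numbers if ``differences`` is a plain array.
    log_base : float
        Base of the logarithm; natural log by default.
    """

    def __init__(self, differences, cycles=None, log_base: float = math.e):
        if isinstance(differences, pd.Series) and cycles is None:
            cycles = differences.index.to_numpy()
            differences = differences.to_numpy()
        if cycles is None:
            raise StatsError("cycle numbers are required")
        self.cycles = np.asarray(cycles, dtype=float)
        self.values = np.asarray(differences, dtype=float)
        self.log_base = float(log_base)
        keep = np.isfinite(self.values) & np.isfinite(self.cycles)
        self.cycles, self.values = self.cycles[keep], self.values[keep]
        if np.any(self.cycles < 1):
            raise StatsError("cycle indices must be >= 1")
        if len(np.unique(self.cycles)) < 2:
            raise StatsError("need >= 2 distinct cycles to fit a learning curve")

    def fit(self) -> LearningCurveResults:
        x = np.log(self.cycles) / np.log(self.log_base)
        slope, intercept = np.polyfit(x, self.values, 1)
        resid = self.values - (slope * x + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((self.values - self.values.mean()) ** 2))
        # zero-variance response: r^2 is undefined, reported missing
        r2 = float("nan") if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        return LearningCurveResults(
            slope=float(slope),
            intercept=float(intercept),
            rsquared=r2,
            n_cycles=len(self.values),
            log_base=self.log_base,
        )


def fit_log_curve(differences, cycles=None, log_base: float = math.e) -> LearningCurveResults:
    """Fit ``a * log(cycle) + b`` by least squares; see :class:`LearningCurve`."""
    return LearningCurve(differences, cycles=cycles, log_base=log_base).fit()


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


def partial_eta_sq(ss_effect: float, ss_residual: float) -> float:
    """Partial eta-squared: SS_effect / (SS_effect + SS_residual)."""
    if ss_effect < 0 or ss_residual < 0:
        raise StatsError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_residual == 0:
        raise StatsError("partial eta-squared undefined when both SS are zero")
    return ss_effect / (ss_effect + ss_residual)


def error_df(n_units: int, df_factor: int) -> int:
    """Within-effect error df under the (n - 1) * df_factor bookkeeping.

    With one continuous 1-df covariate this equals the partition's residual
    df ``df_factor * (n_cycles - 2)`` evaluated at ``n_units = n_cycles - 1``.
    """
    return (n_units - 1) * df_factor


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast matrix, columns orthogonal to ones."""
    h = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))[0]
    return h[:, 1:]


@dataclass
class AnovaResults:
    """Repeated-measures ANOVA summary.

    ``anova_table`` holds one row per effect plus a Residual row per
    within-factor stratum, with Type-III sum of squares, df, mean square, F,
    p and partial eta-squared.  Rows satisfy ``mean_sq = sum_sq / df``,
    ``F = mean_sq / residual mean_sq`` and the partial eta-squared identity
    exactly.
    """

    anova_table: pd.DataFrame
    n_units: int
    covariates: tuple[str, ...]
    dropped_cycles: tuple[int, ...] = ()

    def effect(self, name: str) -> pd.Series:
        sel = self.anova_table[self.anova_table["Source"] == name]
        if sel.empty:
            raise KeyError(name)
        return sel.iloc[0]

    def pvalue(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def summary(self) -> str:
        lines = [
            "Repeated-measures ANOVA (Type III, balanced within-subject partition)",
            f"observational units: {self.n_units} cycles"
            + (f" (dropped incomplete: {list(self.dropped_cycles)})" if self.dropped_cycles else ""),
            f"covariates: {', '.join(self.covariates) if self.covariates else 'none'}",
            "",
        ]
        with pd.option_context("display.float_format", lambda v: f"{v:.5g}"):
            lines.append(self.anova_table.to_string(index=False, na_rep=""))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.anova_table.to_csv(path, index=False)


class RepeatedMeasuresAnova:
    """Two-way within-subject ANOVA with continuous covariates.

    The observational unit is the cycle; within factors are day condition
    (Light1/Light2/Dark) and time-of-day (pre-light/light-on/post-light).
    Covariates (cycle number, optionally day length) are centered and enter
    each within-factor stratum with df equal to the factor df, exactly the
    bookkeeping of the study design.  Cycles with any missing cell are
    dropped listwise.

    Parameters
    ----------
    table : CellTable
    covariates : sequence of {"cycle", "day_length"}
    within : which within factors to include; default both.
    """

    FACTOR_LABELS = {"condition": "Day condition", "interval": "Time-of-day"}

    def __init__(
        self,
        table: CellTable,
        covariates: Sequence[str] = ("cycle",),
        within: Sequence[str] = ("interval", "condition"),
        interval: str | None = None,
    ):
        self.table = table
        self.covariates = tuple(covariates)
        self.within = tuple(within)
        self.interval = interval
        for cov in self.covariates:
            if cov not in ("cycle", "day_length"):
                raise StatsError(f"unknown covariate {cov!r}")

        data = table.data
        if interval is not None:
            if "interval" in self.within:
                self.within = tuple(w for w in self.within if w != "interval")
            data = data[data["interval"] == interval]
            if data.empty:
                raise StatsError(f"no cells for interval {interval!r}")
        if not self.within:
            raise StatsError("need at least one within factor")
        self._data = data

    def fit(self) -> AnovaResults:
        data = self._data
        wide = data.pivot_table(
            index="cycle", columns=["condition", "interval"], values="mean", dropna=False
        )
        complete = wide.dropna()
        dropped = tuple(int(c) for c in wide.index.difference(complete.index))
        n = len(complete)
        p = len(self.covariates)
        if n < 2:
            raise StatsError("need >= 2 complete observational units (cycles)")
        if n - 1 - p < 1:
            raise StatsError(
                f"{n} cycles cannot support {p} covariate(s): no residual df left"
            )

        cycles = complete.index.to_numpy(dtype=float)
        cov_values = {"cycle": cycles}
        if "day_length" in self.covariates:
            dl = self.table.day_lengths().reindex(complete.index).to_numpy(dtype=float)
            if np.any(~np.isfinite(dl)):
                raise StatsError("day_length covariate requested but missing from table")
            cov_values["day_length"] = dl
        x = np.column_stack([cov_values[c] for c in self.covariates]) if p else np.empty((n, 0))
        x = x - x.mean(axis=0, keepdims=True)

        conditions = sorted({c for c, _ in wide.columns}, key=list(CONDITIONS).index)
        intervals = sorted({i for _, i in wide.columns}, key=list(INTERVALS).index)
        # y indexed [cycle, condition, interval]
        y = np.stack(
            [
                np.column_stack([complete[(c, i)].to_numpy() for i in intervals])
                for c in conditions
            ],
            axis=1,
        )

        c_cond = _orthonormal_contrasts(len(conditions))
        c_int = _orthonormal_contrasts(len(intervals))

        strata: list[tuple[str, np.ndarray, float]] = []
        if "interval" in self.within:
            z = np.einsum("nci,iq->nq", y, c_int) / len(conditions)
            strata.append(("Time-of-day", z, float(len(conditions))))
        if "condition" in self.within:
            z = np.einsum("nci,cq->nq", y, c_cond) / len(intervals)
            strata.append(("Day condition", z, float(len(intervals))))
        if "interval" in self.within and "condition" in self.within:
            ckron = np.einsum("cq,ir->ciqr", c_cond, c_int).reshape(
                len(conditions) * len(intervals), -1
            )
            z = y.reshape(n, -1) @ ckron
            strata.append(("Time-of-day × Day condition", z, 1.0))

        rows = []
        cov_labels = {"cycle": "cycle", "day_length": "day length"}
        for name, z, m in strata:
            q = z.shape[1]
            rows.extend(self._stratum_rows(name, z, m, x, cov_labels))
        table = pd.DataFrame(
            rows,
            columns=["Source", "sum_sq", "df", "mean_sq", "F", "p", "partial_eta_sq"],
        )
        return AnovaResults(
            anova_table=table,
            n_units=n,
            covariates=self.covariates,
            dropped_cycles=dropped,
        )

    def _stratum_rows(self, name, z, m, x, cov_labels):
        n, q = z.shape
        p = x.shape[1]
        design = np.column_stack([np.ones(n), x])

        beta, *_ = np.linalg.lstsq(design, z, rcond=None)
        resid = z - design @ beta
        rss_full = float(np.sum(resid**2))

        ss_effect = m * n * float(np.sum(z.mean(axis=0) ** 2))
        ss_res = m * rss_full
        df_res = q * (n - 1 - p)
        ms_res = ss_res / df_res

        def row(source, ss, df):
            ms = ss / df
            f = ms / ms_res
            pval = float(sps.f.sf(f, df, df_res))
            return {
                "Source": source,
                "sum_sq": ss,
                "df": df,
                "mean_sq": ms,
                "F": f,
                "p": pval,
                "partial_eta_sq": partial_eta_sq(ss, ss_res) if ss or ss_res else np.nan,
            }

        rows = [row(name, ss_effect, q)]
        for j, cov in enumerate(self.covariates):
            keep = [0] + [1 + jj for jj in range(p) if jj != j]
            sub = design[:, keep]
            beta_j, *_ = np.linalg.lstsq(sub, z, rcond=None)
            rss_drop = float(np.sum((z - sub @ beta_j) ** 2))
            ss_cov = m * max(rss_drop - rss_full, 0.0)
            rows.append(row(f"{name} × {cov_labels[cov]}", ss_cov, q))
        rows.append(
            {
                "Source": "Residual",
                "sum_sq": ss_res,
                "df": df_res,
                "mean_sq": ms_res,
                "F": np.nan,
                "p": np.nan,
                "partial_eta_sq": np.nan,
            }
        )
        return rows


def rm_anova(
    table: CellTable, covariates: Sequence[str] = ("cycle",)
) -> AnovaResults:
    """Full condition x interval repeated-measures ANOVA with covariates."""
    return RepeatedMeasuresAnova(table, covariates=covariates).fit()


def simple_effects(
    table: CellTable, interval: str, covariates: Sequence[str] = ("cycle",)
) -> AnovaResults:
    """Condition x covariate ANOVA restricted to one time-of-day interval."""
    if interval not in INTERVALS:
        raise StatsError(f"unknown interval {interval!r}")
    return RepeatedMeasuresAnova(
        table, covariates=covariates, within=("condition",), interval=interval
    ).fit()


# ---------------------------------------------------------------------------
# Day-length stratification
# ---------------------------------------------------------------------------


@dataclass
class StratumSummary:
    """Summary of the motion differences of one day-length stratum."""

    cycles: tuple[int, ...]
    n_cycles: int
    mean_difference: float
    fit: LearningCurveResults | None = None


def stratify_by_day_length(
    differences: pd.Series,
    day_lengths: pd.Series | Mapping[int, float],
    band: tuple[float, float] = (12.0, 24.0),
    log_base: float = math.e,
) -> dict[str, StratumSummary]:
    """Split per-cycle differences by day length inside/outside ``band``.

    The band is inclusive at both ends (a 12-h or 24-h day is in-band).  The
    in-band group additionally gets a learning-curve fit on the original
    cycle numbers when at least two cycles are available.
    """
    if len(differences) == 0:
        raise StatsError("no differences to stratify")
    if not isinstance(day_lengths, pd.Series):
        day_lengths = pd.Series(dict(day_lengths))
    lo, hi = band
    out: dict[str, StratumSummary] = {}
    n_by_cycle = day_lengths.reindex(differences.index)
    in_band = (n_by_cycle >= lo) & (n_by_cycle <= hi)
    for key, mask in (("in_band", in_band), ("out_of_band", ~in_band)):
        d = differences[mask].dropna()
        fit = None
        if key == "in_band" and len(np.unique(d.index)) >= 2:
            fit = fit_log_curve(d, log_base=log_base)
        out[key] = StratumSummary(
            cycles=tuple(int(c) for c in d.index),
            n_cycles=len(d),
            mean_difference=float(d.mean()) if len(d) else float("nan"),
            fit=fit,
        )
    return out
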