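"""Observer-timing analysis: normalization and metric-vs-time regressions.

The validation design behind this module: several observers adjust each
simulated contour into a clinically acceptable one and record the time
taken.  Absolute times vary widely between observers, so each observer's
adjustment times are normalized by that observer's own time to contour the
organ from scratch; the normalized times are then regressed (ordinary
least squares) on a contour-quality metric, per observer and pooled over
per-case observer means.  A good effort metric should predict normalized
time with a single strong linear trend across all contour sets; the
untouched-point fraction (HSC) does, the Dice coefficient does not.

The module works on tidy :class:`pandas.DataFrame` tables and ships the
study's observer-timing and metric tables as packaged CSV fixtures.
Printed normalized times in the fixture are never trusted: they are
recomputed from the absolute seconds and only used as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError

#: predictor span below which a fit is flagged as near-degenerate
DEGENERATE_SPAN = 0.02

_CASE_KEY = ["contour_set", "case"]


@dataclass(frozen=True)
class TimingRecord:
    """One observer × case timing entry."""

    observer: str
    contour_set: int
    case: int
    seconds: float
    scratch_seconds: float

    @property
    def normalized(self) -> float:
        return self.seconds / self.scratch_seconds


@dataclass(frozen=True)
class RegressionResult:
    """An ordinary-least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


@dataclass
class StudyReport:
    """Per-observer and pooled fits of normalized time on a metric."""

    predictor: str
    per_observer: dict[str, RegressionResult]
    pooled: RegressionResult
    scatter: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "per_observer": {k: v.to_dict() for k, v in self.per_observer.items()},
            "pooled": self.pooled.to_dict(),
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------
def _data_path(name: str):
    return resources.files("contourhsc.data").joinpath(name)


def load_metric_table(path=None) -> pd.DataFrame:
    """Per-observer HSC/DSC table (long form); packaged study table by default.

    Rows with observer == "AVE" are the printed per-case means, kept for
    cross-checking; analysis recomputes means from the observer rows.
    """
    src = path if path is not None else _data_path("table1_metrics.csv")
    df = pd.read_csv(src, dtype={"observer": str})
    required = {"contour_set", "case", "observer", "hsc", "dsc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    return df


def load_timing_table(path=None) -> pd.DataFrame:
    """Observer-timing table; packaged study table by default.

    Columns: contour_set, case, observer, seconds, scratch_seconds, and
    (fixture only) normalized_printed for cross-checks.
    """
    src = path if path is not None else _data_path("table2_timing.csv")
    df = pd.read_csv(src, dtype={"observer": str})
    required = {"contour_set", "case", "observer", "seconds", "scratch_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"timing table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------
def round_half_up(x, decimals: int = 3):
    """Decimal round-half-up (the rounding used by the printed tables)."""
    factor = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def normalize_times(timing: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized`` column: seconds / same-observer scratch seconds.

    Rows without absolute seconds (e.g. printed AVE rows) are dropped.
    """
    df = timing.dropna(subset=["seconds"]).copy()
    if df["scratch_seconds"].isna().any() or (df["scratch_seconds"] <= 0).any():
        raise ValueError("every observer needs a positive from-scratch time")
    df["normalized"] = df["seconds"] / df["scratch_seconds"]
    return df


def fit_linear(x, y, label: str = "") -> RegressionResult:
    """Ordinary least squares of y on x with R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("fit_linear needs equal-length inputs with n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor is constant; OLS line undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        label=label,
    )


def max_min_ratio(values) -> float:
    """max/min of a list of positive numbers, to 2 decimals."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("max_min_ratio needs a nonempty all-positive list")
    return float(round_half_up(v.max() / v.min(), 2))


def aggregate_observers(df: pd.DataFrame, value: str, decimals: int | None = 3) -> pd.DataFrame:
    """Arithmetic per-case mean of ``value`` over observers.

    The table must be complete (same observers for every case).  Means are
    taken on unrounded values and then rounded half-up (the printed-table
    convention); pass ``decimals=None`` to skip rounding.
    """
    obs = df[df["observer"] != "AVE"]
    counts = obs.groupby(_CASE_KEY)[value].count()
    if counts.nunique() > 1:
        raise ValueError("incomplete table: per-case observer counts differ")
    if obs[value].isna().any():
        raise ValueError(f"missing {value!r} cells")
    out = obs.groupby(_CASE_KEY, as_index=False)[value].mean()
    if decimals is not None:
        out[value] = round_half_up(out[value], decimals)
    return out


def run_study(
    metric_table: pd.DataFrame,
    timing_table: pd.DataFrame,
    predictor: str = "hsc",
) -> StudyReport:
    """Fit normalized modification time against a metric, per observer and pooled.

    ``metric_table`` and ``timing_table`` must share (contour_set, case)
    keys and observer labels.  The pooled fit regresses per-case observer
    means of normalized time on per-case means of the predictor.
    """
    predictor = predictor.lower()
    if predictor not in ("hsc", "dsc"):
        raise ValueError("predictor must be 'hsc' or 'dsc'")
    timing = normalize_times(timing_table)
    met = metric_table[metric_table["observer"] != "AVE"]
    merged = met.merge(timing, on=_CASE_KEY + ["observer"], how="outer", indicator=True)
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        keys = bad[_CASE_KEY + ["observer"]].to_dict("records")
        raise ValueError(f"metric/timing tables do not align; unmatched: {keys}")
    merged = merged.drop(columns="_merge")

    warnings_out: list[str] = []
    per_observer: dict[str, RegressionResult] = {}
    for obs, grp in merged.groupby("observer"):
        x = grp[predictor].to_numpy()
        span = float(np.ptp(x))
        if span < DEGENERATE_SPAN:
            warnings_out.append(
                f"observer {obs}: {predictor} spans only {span:.3f}; "
                "fit is near-degenerate"
            )
        if span == 0:
            raise DegenerateFitError(
                f"observer {obs}: {predictor} is constant across cases"
            )
        fit = fit_linear(x, grp["normalized"].to_numpy(), label=f"Obs{obs}")
        if fit.r_squared < 0.5:
            warnings_out.append(
                f"observer {obs}: weak fit (R²={fit.r_squared:.3f}); "
                f"{predictor} does not predict normalized time"
            )
        per_observer[str(obs)] = fit

    mean_x = aggregate_observers(met, predictor)
    mean_y = aggregate_observers(timing, "normalized")
    pooled_df = mean_x.merge(mean_y, on=_CASE_KEY)
    pooled = fit_linear(
        pooled_df[predictor].to_numpy(),
        pooled_df["normalized"].to_numpy(),
        label="pooled",
    )
    scatter = merged[_CASE_KEY + ["observer", predictor, "normalized"]].copy()
    return StudyReport(
        predictor=predictor,
        per_observer=per_observer,
        pooled=pooled,
        scatter=scatter,
        warnings=warnings_out,
    )


def plot_study(report: StudyReport, path) -> None:
    """Scatter of normalized time vs the predictor with per-observer fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for obs, grp in report.scatter.groupby("observer"):
        ax.scatter(grp[report.predictor], grp["normalized"], s=18, label=f"Obs {obs}")
        fit = report.per_observer[str(obs)]
        xs = np.linspace(grp[report.predictor].min(), grp[report.predictor].max(), 2)
        ax.plot(xs, fit.slope * xs + fit.intercept, lw=1, alpha=0.7)
    ax.set_xlabel(report.predictor.upper())
    ax.set_ylabel("normalized modification time")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
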