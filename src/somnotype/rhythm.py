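"""Chi-square periodogram circadian analysis.

The rhythm statistic is the classical folded-variance periodogram: for a
candidate period of P bins over a series of N bins, the data are folded
into P phase columns and

    Qp = N * sum_h K_h * (M_h - M)^2 / sum_i (x_i - M)^2

where M_h is the mean and K_h the sample count of phase column h and M is
the grand mean. Under the white-noise null Qp is asymptotically
chi-square with P - 1 degrees of freedom, so each candidate period gets a
per-period significance line at the chi-square inverse CDF of 1 - alpha —
the single rising diagonal of the classical periodogram plot (no
correction across candidate periods, matching that convention).

The free-running period tau is the candidate period with the largest Qp
inside the search window, reported only when it exceeds its significance
line; ties break toward the shorter period.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import (
    ActivityTrace,
    LightingSchedule,
    ParameterError,
    Periodogram,
    SECONDS_PER_DAY,
    SECONDS_PER_HOUR,
)

#: Default candidate-period windows (hours).
MOUSE_PERIOD_RANGE_H = (20.0, 28.0)
DIARY_PERIOD_RANGE_H = (16.0, 120.0)

#: Mouse traces are averaged down to 6-min analysis bins before the
#: periodogram (0.1 h period resolution).
DEFAULT_ANALYSIS_BIN_S = 360


def downsample(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean-downsample by an integer factor, dropping a trailing remainder."""
    if factor < 1:
        raise ParameterError("downsample factor must be >= 1")
    n = (values.size // factor) * factor
    if n == 0:
        raise ParameterError("series shorter than one analysis bin")
    return values[:n].reshape(-1, factor).mean(axis=1)


def _qp(series: np.ndarray, period_bins: int) -> float:
    n = series.size
    phase = np.arange(n) % period_bins
    counts = np.bincount(phase, minlength=period_bins).astype(float)
    sums = np.bincount(phase, weights=series, minlength=period_bins)
    grand = series.mean()
    ss_tot = float(((series - grand) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0  # constant series: no rhythm, Qp defined as 0
    col_means = sums / counts
    return float(n * (counts * (col_means - grand) ** 2).sum() / ss_tot)


class ChiSquarePeriodogram(BaseEstimator):
    """Chi-square periodogram estimator over an integer-bin period grid.

    Parameters
    ----------
    period_range_h : (float, float)
        Inclusive window of candidate periods, hours.
    step_bins : int
        Grid step in analysis bins (1 bin = ``bin_seconds`` of period
        resolution, e.g. 0.1 h for 6-min bins).
    alpha : float
        Per-period significance level for the chi-square line.
    bin_seconds : float
        Width of the analysis bins of the input series.

    Fitted attributes
    -----------------
    periods_h_, qp_, df_, threshold_ : arrays over the candidate grid.
    tau_h_ : significant peak period within the grid, or None.
    peak_qp_, significant_ : peak statistic and its significance flag.
    """

    def __init__(
        self,
        period_range_h: tuple[float, float] = MOUSE_PERIOD_RANGE_H,
        step_bins: int = 1,
        alpha: float = 0.01,
        bin_seconds: float = DEFAULT_ANALYSIS_BIN_S,
    ):
        self.period_range_h = period_range_h
        self.step_bins = step_bins
        self.alpha = alpha
        self.bin_seconds = bin_seconds

    def _period_grid(self, n_bins: int) -> np.ndarray:
        lo_h, hi_h = self.period_range_h
        if not (0 < lo_h < hi_h):
            raise ParameterError("period range must satisfy 0 < lo < hi")
        lo = int(np.ceil(lo_h * SECONDS_PER_HOUR / self.bin_seconds))
        hi = int(np.floor(hi_h * SECONDS_PER_HOUR / self.bin_seconds))
        lo = max(lo, 2)
        if hi > n_bins // 2:
            raise ParameterError(
                f"max candidate period ({hi} bins) exceeds half the series "
                f"({n_bins} bins); record longer or narrow the range"
            )
        if hi < lo:
            raise ParameterError("period range contains no candidate period")
        return np.arange(lo, hi + 1, self.step_bins)

    def fit(self, series: np.ndarray, y=None) -> "ChiSquarePeriodogram":
        series = np.asarray(series, dtype=float)
        if series.ndim != 1 or series.size < 4:
            raise ParameterError("series must be a 1-D array of >= 4 bins")
        grid = self._period_grid(series.size)
        qp = np.array([_qp(series, int(p)) for p in grid])
        df = grid - 1
        threshold = stats.chi2.ppf(1.0 - self.alpha, df)
        self.periods_h_ = grid * self.bin_seconds / SECONDS_PER_HOUR
        self.qp_ = qp
        self.df_ = df
        self.threshold_ = threshold
        sig = qp > threshold
        # argmax ties break toward the shorter period (first index)
        peak = int(np.argmax(qp))
        self.peak_qp_ = float(qp[peak])
        self.significant_ = bool(sig[peak])
        self.tau_h_ = float(self.periods_h_[peak]) if sig[peak] else None
        return self

    def to_periodogram(self) -> Periodogram:
        return Periodogram(
            periods_h=self.periods_h_,
            qp=self.qp_,
            df=self.df_,
            threshold=self.threshold_,
            alpha=self.alpha,
            bin_seconds=self.bin_seconds,
        )


def chi_square_periodogram(
    series: np.ndarray,
    period_range_h: tuple[float, float],
    step_bins: int = 1,
    alpha: float = 0.01,
    analysis_bin_s: float = DEFAULT_ANALYSIS_BIN_S,
) -> Periodogram:
    """Functional wrapper around :class:`ChiSquarePeriodogram`."""
    est = ChiSquarePeriodogram(
        period_range_h=period_range_h,
        step_bins=step_bins,
        alpha=alpha,
        bin_seconds=analysis_bin_s,
    )
    return est.fit(series).to_periodogram()


def estimate_tau(
    pg: Periodogram, search_range_h: Optional[tuple[float, float]] = None
) -> Optional[float]:
    """Significant peak period within the search window, else None.

    Ties in Qp break toward the shorter period.
    """
    lo, hi = search_range_h if search_range_h else (pg.periods_h[0], pg.periods_h[-1])
    m = (pg.periods_h >= lo) & (pg.periods_h <= hi)
    if not m.any():
        raise ParameterError("periodogram does not cover the search range")
    qp = pg.qp[m]
    peak = int(np.argmax(qp))
    if qp[peak] <= pg.threshold[m][peak]:
        return None
    return float(pg.periods_h[m][peak])


def double_plot_actogram(series: np.ndarray, bins_per_day: int) -> np.ndarray:
    """Double-plotted actogram matrix for rendering.

    Row i holds day i followed by day i + 1 (each day plotted twice: in
    the right half of one row and the left half of the next). Values are
    normalised to [0, 1]; the right half of the last row is NaN-padded.
    ``bins_per_day`` may correspond to any modulo period (24 h or tau).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ParameterError("empty series")
    n_days = int(np.ceil(series.size / bins_per_day))
    if n_days < 2:
        raise ParameterError("need at least 2 plotted days")
    padded = np.full(n_days * bins_per_day, np.nan)
    padded[: series.size] = series
    vmax = np.nanmax(padded)
    if vmax > 0:
        padded = padded / vmax
    days = padded.reshape(n_days, bins_per_day)
    out = np.full((n_days, 2 * bins_per_day), np.nan)
    out[:, :bins_per_day] = days
    out[:-1, bins_per_day:] = days[1:]
    return out


def tau_adjusted_daily_activity(
    trace_values: np.ndarray,
    tau_h: Optional[float],
    bin_seconds: float,
) -> tuple[float, bool]:
    """Daily average activity scaled by (24 / tau).

    Expressing each subject's daily activity per 24 h of its own internal
    cycle makes activity totals comparable across subjects free-running at
    different periods. Returns (value, adjusted_flag); when tau is None
    (arrhythmic subject) the unadjusted daily mean is propagated with
    adjusted_flag False.
    """
    values = np.asarray(trace_values, dtype=float)
    bins_per_day = int(SECONDS_PER_DAY / bin_seconds)
    n_days = values.size / bins_per_day
    daily = values.sum() / n_days if n_days > 0 else 0.0
    if tau_h is None:
        return float(daily), False
    if tau_h <= 0:
        raise ParameterError("tau must be positive")
    return float(24.0 / tau_h * daily), True


def light_response_table(
    traces: Sequence[ActivityTrace],
    schedule: LightingSchedule | None = None,
    period_range_h: tuple[float, float] = MOUSE_PERIOD_RANGE_H,
    analysis_bin_s: int = DEFAULT_ANALYSIS_BIN_S,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per subject x constant-lighting-condition (tau, adjusted activity).

    Each analysis-grade (>= 9 day) DD/LL block of the schedule is analysed
    separately with the chi-square periodogram; shorter blocks are skipped
    with a warning. The output is tidy, ready for the repeated-measures
    ANOVA layer: columns subject, genotype, condition, lux, tau_h,
    peak_qp, significant, mean_daily_activity, tau_adjusted_activity.
    """
    rows = []
    for trace in traces:
        sched = schedule or trace.schedule
        if sched is None:
            raise ParameterError(f"no schedule for subject {trace.subject_id}")
        factor = int(analysis_bin_s // trace.bin_seconds)
        for block in sched.blocks:
            if block.condition == "LD":
                continue
            if not block.analysis_grade:
                warnings.warn(
                    f"{trace.subject_id}: {block.condition} block of "
                    f"{block.duration_days:g} days < 9 days — excluded",
                    stacklevel=2,
                )
                continue
            i0 = int((block.start_s - trace.start_time) / trace.bin_seconds)
            i1 = int((block.end_s - trace.start_time) / trace.bin_seconds)
            seg = trace.values[max(i0, 0) : min(i1, trace.n_bins)]
            if seg.size == 0:
                warnings.warn(
                    f"{trace.subject_id}: no data in block at {block.start_s}s",
                    stacklevel=2,
                )
                continue
            series = downsample(seg, factor)
            est = ChiSquarePeriodogram(
                period_range_h=period_range_h,
                alpha=alpha,
                bin_seconds=analysis_bin_s,
            ).fit(series)
            adj, flag = tau_adjusted_daily_activity(seg, est.tau_h_, trace.bin_seconds)
            bins_per_day = SECONDS_PER_DAY / trace.bin_seconds
            rows.append(
                {
                    "subject": trace.subject_id,
                    "genotype": trace.genotype,
                    "condition": block.condition,
                    "lux": block.effective_lux,
                    "tau_h": est.tau_h_,
                    "peak_qp": est.peak_qp_,
                    "significant": est.significant_,
                    "mean_daily_activity": seg.sum() / (seg.size / bins_per_day),
                    "tau_adjusted_activity": adj if flag else np.nan,
                }
            )
    return pd.DataFrame(rows)
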