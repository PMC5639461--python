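"""Behavioural sleep scoring from immobility.

Sleep is called on sustained absence of sensor-detected movement: a run of
at least 4 consecutive 10-s bins with no activity (>= 40 s immobile).
Two onset conventions are exposed, because the two published phrasings of
the rule differ in whether the first 30 s of a qualifying run count as
sleep:

* ``fourth_bin`` (default, literal reading): sleep starts at the fourth
  immobile bin, so a run of R >= 4 bins contributes R − 3 sleep bins.
* ``run_start``: the whole qualifying run is sleep (R bins), as in much of
  the 40-s immobility literature.

The total-sleep difference between the conventions is exactly 30 s per
sleep bout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    ActivityTrace,
    LightingSchedule,
    ParameterError,
    SECONDS_PER_HOUR,
    SleepSeries,
)

ONSET_CONVENTIONS = ("fourth_bin", "run_start")


def _run_lengths(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean mask -> (run start indices, run lengths)
    for the True runs."""
    if mask.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    padded = np.diff(np.r_[False, mask, False].astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return starts, ends - starts


class SleepScorer(BaseEstimator, TransformerMixin):
    """Immobility-rule sleep scorer (stateless transformer).

    Parameters
    ----------
    immobility_threshold_bins : int
        Minimum run of immobile bins before sleep is called (4 bins of
        10 s = the 40-s rule).
    onset : {"fourth_bin", "run_start"}
        Whether sleep starts at the threshold bin or at the start of the
        immobile run.
    epsilon : float
        A bin counts as active when percent-active > epsilon. The sensor
        protocol defines activity as any detected movement, so the default
        is 0.
    """

    def __init__(
        self,
        immobility_threshold_bins: int = 4,
        onset: str = "fourth_bin",
        epsilon: float = 0.0,
    ):
        self.immobility_threshold_bins = immobility_threshold_bins
        self.onset = onset
        self.epsilon = epsilon

    def _validate(self) -> None:
        if self.onset not in ONSET_CONVENTIONS:
            raise ParameterError(f"onset must be one of {ONSET_CONVENTIONS}")
        if self.immobility_threshold_bins < 1:
            raise ParameterError("immobility threshold must be >= 1 bin")

    def fit(self, X=None, y=None):  # stateless; kept for pipeline compatibility
        self._validate()
        self.n_features_in_ = 1
        return self

    def transform(self, trace: ActivityTrace) -> SleepSeries:
        self._validate()
        if trace.bin_seconds != 10:
            raise ParameterError(
                "the immobility rule is defined on 10-s bins; "
                f"got bin_seconds={trace.bin_seconds}"
            )
        immobile = trace.values <= self.epsilon
        flags = np.zeros(trace.n_bins, dtype=bool)
        starts, lengths = _run_lengths(immobile)
        thr = self.immobility_threshold_bins
        for s, ln in zip(starts, lengths):
            if ln >= thr:
                if self.onset == "fourth_bin":
                    flags[s + thr - 1 : s + ln] = True
                else:
                    flags[s : s + ln] = True
        return SleepSeries(
            subject_id=trace.subject_id,
            flags=flags,
            bin_seconds=trace.bin_seconds,
            start_time=trace.start_time,
            immobility_threshold_bins=thr,
            onset=self.onset,
        )


def score_sleep(trace: ActivityTrace, onset: str = "fourth_bin", epsilon: float = 0.0) -> SleepSeries:
    """Functional wrapper around :class:`SleepScorer`."""
    return SleepScorer(onset=onset, epsilon=epsilon).fit().transform(trace)


def daily_sleep_activity_profile(
    trace: ActivityTrace,
    sleep: SleepSeries,
    schedule: LightingSchedule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """24-h profiles and per-day light/dark totals.

    Returns
    -------
    profile : DataFrame indexed by hour-of-day (0–23) with columns
        ``activity_mean`` (mean percent-active) and ``sleep_fraction``
        (fraction of the hour asleep), averaged over complete days.
    daily : DataFrame with one row per complete day and columns
        ``activity_light``, ``activity_dark`` (summed percent-active) and
        ``sleep_light_h``, ``sleep_dark_h`` (hours of sleep per period).
    """
    schedule = schedule or trace.schedule
    if schedule is None:
        raise ParameterError("a lighting schedule is required for the profile")
    bins_per_day = 86_400 // trace.bin_seconds
    n_days = trace.n_bins // bins_per_day
    if n_days < 1:
        raise ParameterError("at least one complete day is required")
    if trace.n_bins % bins_per_day:
        warnings.warn(
            f"trailing partial day ({trace.n_bins % bins_per_day} bins) "
            "excluded from the daily profile",
            stacklevel=2,
        )
    n = n_days * bins_per_day
    act = trace.values[:n].reshape(n_days, bins_per_day)
    slp = sleep.flags[:n].reshape(n_days, bins_per_day)

    bins_per_hour = SECONDS_PER_HOUR // trace.bin_seconds
    hourly_act = act.reshape(n_days, 24, bins_per_hour).mean(axis=2)
    hourly_slp = slp.reshape(n_days, 24, bins_per_hour).mean(axis=2)
    profile = pd.DataFrame(
        {
            "activity_mean": hourly_act.mean(axis=0),
            "sleep_fraction": hourly_slp.mean(axis=0),
        },
        index=pd.Index(range(24), name="hour"),
    )

    dark = schedule.is_dark(trace.bin_times()[:n]).reshape(n_days, bins_per_day)
    bin_h = trace.bin_seconds / SECONDS_PER_HOUR
    daily = pd.DataFrame(
        {
            "activity_light": (act * ~dark).sum(axis=1),
            "activity_dark": (act * dark).sum(axis=1),
            "sleep_light_h": (slp * ~dark).sum(axis=1) * bin_h,
            "sleep_dark_h": (slp * dark).sum(axis=1) * bin_h,
        },
        index=pd.Index(range(n_days), name="day"),
    )
    return profile, daily
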