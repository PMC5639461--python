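"""Bout segmentation and categorisation.

A bout of activity is one or more consecutive 10-s bins in which the
animal was active; its intensity is the mean per-bin percent-active over
the bout (the percentage of the whole bout that the sensor was active).
A bout of sleep is a maximal run of sleep-flagged bins from the
immobility rule. Bout lengths are tabulated into the four standard
classes: < 1 min, 1–10 min, 10 min – 1 h and > 1 h.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .sleep import _run_lengths
from .types import ActivityTrace, Bout, ParameterError, SleepSeries

#: Half-open length category edges, seconds: [0,60), [60,600), [600,3600), [3600,inf)
DEFAULT_LENGTH_EDGES_S = (0.0, 60.0, 600.0, 3600.0, math.inf)
DEFAULT_LENGTH_LABELS = ("<1 min", "1-10 min", "10 min-1 h", ">1 h")

#: Default intensity deciles for activity bouts, percent.
DEFAULT_INTENSITY_EDGES = tuple(float(x) for x in range(0, 101, 10))


def segment_activity_bouts(trace: ActivityTrace, epsilon: float = 0.0) -> list[Bout]:
    """Maximal runs of active bins, with per-bout mean intensity."""
    active = trace.values > epsilon
    starts, lengths = _run_lengths(active)
    cum = np.r_[0.0, np.cumsum(trace.values)]
    bouts = []
    for s, ln in zip(starts, lengths):
        intensity = (cum[s + ln] - cum[s]) / ln
        bouts.append(
            Bout(
                kind="activity",
                start_bin=int(s),
                n_bins=int(ln),
                bin_seconds=trace.bin_seconds,
                intensity=float(intensity),
            )
        )
    return bouts


def segment_sleep_bouts(sleep: SleepSeries) -> list[Bout]:
    """Maximal runs of sleep-flagged bins."""
    starts, lengths = _run_lengths(sleep.flags)
    return [
        Bout(kind="sleep", start_bin=int(s), n_bins=int(ln), bin_seconds=sleep.bin_seconds)
        for s, ln in zip(starts, lengths)
    ]


def categorize_bouts(
    bouts: list[Bout],
    length_edges_s: tuple[float, ...] = DEFAULT_LENGTH_EDGES_S,
    labels: tuple[str, ...] | None = None,
) -> pd.Series:
    """Count bouts per half-open duration category [lo, hi).

    The last category is open-ended, so every bout falls in exactly one
    category and the counts sum to the number of bouts.
    """
    edges = np.asarray(length_edges_s, dtype=float)
    if edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ParameterError("length edges must be strictly increasing")
    if labels is None:
        labels = (
            DEFAULT_LENGTH_LABELS
            if tuple(edges) == DEFAULT_LENGTH_EDGES_S
            else tuple(f"[{lo:g}, {hi:g}) s" for lo, hi in zip(edges[:-1], edges[1:]))
        )
    if len(labels) != edges.size - 1:
        raise ParameterError("need one label per category")
    durations = np.array([b.duration_s for b in bouts], dtype=float)
    idx = np.searchsorted(edges[1:-1], durations, side="right")
    counts = np.bincount(idx, minlength=len(labels)) if durations.size else np.zeros(len(labels), dtype=int)
    return pd.Series(counts, index=pd.Index(labels, name="category"), name="count")


def categorize_intensities(
    bouts: list[Bout],
    intensity_edges: tuple[float, ...] = DEFAULT_INTENSITY_EDGES,
) -> pd.Series:
    """Count activity bouts per half-open intensity decile (last bin closed
    at 100)."""
    edges = np.asarray(intensity_edges, dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ParameterError("intensity edges must be strictly increasing")
    vals = np.array(
        [b.intensity for b in bouts if b.kind == "activity"], dtype=float
    )
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = f"[{edges[-2]:g}, {edges[-1]:g}]"
    idx = np.clip(np.searchsorted(edges[1:-1], vals, side="right"), 0, len(labels) - 1)
    counts = np.bincount(idx, minlength=len(labels)) if vals.size else np.zeros(len(labels), dtype=int)
    return pd.Series(counts, index=pd.Index(labels, name="intensity"), name="count")


def bout_category_table(
    entries: list[tuple[str, str, str, list[Bout]]],
    days_observed: float,
    length_edges_s: tuple[float, ...] = DEFAULT_LENGTH_EDGES_S,
) -> pd.DataFrame:
    """Tidy per-subject bout-category table.

    ``entries`` holds (subject, genotype, kind, bouts) tuples. One output
    row per subject x kind x length category, with both the raw count over
    the observation window and the per-day rate (count / days_observed) —
    figure-style summaries may be either, so both are emitted. Subjects
    with no bouts of a kind get an all-zero row per category.
    """
    if days_observed <= 0:
        raise ParameterError("days_observed must be positive")
    rows = []
    for subject_id, genotype, kind, bout_list in entries:
        counts = categorize_bouts(bout_list, length_edges_s)
        for category, count in counts.items():
            rows.append(
                {
                    "subject": subject_id,
                    "genotype": genotype,
                    "kind": kind,
                    "category": category,
                    "count": int(count),
                    "per_day": count / days_observed,
                    "days_observed": days_observed,
                }
            )
    return pd.DataFrame(rows)
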