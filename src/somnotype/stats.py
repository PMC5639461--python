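"""Inferential layer: mixed-design repeated-measures ANOVA with Bonferroni
post-hocs, Welch and log-scale t-tests, and the extra-sum-of-squares
skew-normal comparison of event-amplitude frequency distributions.

The two-way RM-ANOVA is the classical univariate mixed design: one
between-subject factor (genotype), one within-subject factor (bout
category or light level), one observation per subject x level. Subjects
nested in genotype form the error stratum for the between effect; the
subject-by-within residual is the error stratum for the within and
interaction effects. No sphericity correction is applied (equal variance
is assumed, matching the original analysis convention). Percent variation
explained is 100 * SS_effect / SS_total, the Prism-style "% of total
variation".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import ParameterError, ValidationError


# ---------------------------------------------------------------------------
# Two-way mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Mixed-design ANOVA table plus Bonferroni post-hocs.

    ``table`` rows: between (genotype), within, interaction, subject
    (subjects-within-genotype stratum) and residual, with SS, df, F, P and
    percent of total variation. ``posthoc`` has one row per within-level
    (and group pair when > 2 groups) with the raw and Bonferroni-adjusted
    P of the between-group comparison at that level.
    """

    table: pd.DataFrame
    posthoc: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def two_way_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "genotype",
    within: str = "category",
    subject: str = "subject",
) -> AnovaResult:
    """Two-way mixed ANOVA (between x within, repeated over subjects).

    Requires a complete balanced within-design: every subject observed
    exactly once at every within level; >= 2 subjects per group. Missing
    cells raise (no imputation).
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise ValidationError("missing values in the response")
    wide = df.pivot_table(index=[between, subject], columns=within, values=dv,
                          aggfunc="count")
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValidationError(
            "design must be balanced: one observation per subject per level"
        )
    groups = df[between].unique()
    levels = df[within].unique()
    a, b = len(groups), len(levels)
    n_per_group = df.groupby(between)[subject].nunique()
    if (n_per_group < 2).any():
        raise ValidationError(">= 2 subjects per group required")
    if a < 2 or b < 2:
        raise ValidationError("both factors need >= 2 levels")

    grand = df[dv].mean()
    n_total = len(df)
    ss_total = float(((df[dv] - grand) ** 2).sum())

    subj_means = df.groupby([between, subject])[dv].mean()
    group_means = df.groupby(between)[dv].mean()
    level_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()

    # between-subjects stratum
    ss_between_subjects = float(b * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        sum(b * n_per_group[g] * (group_means[g] - grand) ** 2 for g in groups)
    )
    ss_subj = ss_between_subjects - ss_group
    df_group = a - 1
    df_subj = int(n_per_group.sum() - a)

    # within-subjects stratum
    ss_within_factor = float(
        (n_total / b) * ((level_means - grand) ** 2).sum()
    )
    ss_cells = float(
        sum(
            n_per_group[g] * (cell_means[(g, l)] - grand) ** 2
            for g in groups
            for l in levels
        )
    )
    ss_inter = ss_cells - ss_group - ss_within_factor
    ss_resid = ss_total - ss_between_subjects - ss_within_factor - ss_inter
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_resid = df_subj * (b - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj / df_subj
    ms_within = ss_within_factor / df_within
    ms_inter = ss_inter / df_inter
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    def _f_p(ms_num, df_num, ms_den, df_den):
        if ms_den <= 0 or not np.isfinite(ms_den):
            return np.nan, np.nan
        f = ms_num / ms_den
        return f, float(stats.f.sf(f, df_num, df_den))

    f_group, p_group = _f_p(ms_group, df_group, ms_subj, df_subj)
    f_within, p_within = _f_p(ms_within, df_within, ms_resid, df_resid)
    f_inter, p_inter = _f_p(ms_inter, df_inter, ms_resid, df_resid)

    table = pd.DataFrame(
        {
            "SS": [ss_group, ss_within_factor, ss_inter, ss_subj, ss_resid],
            "df": [df_group, df_within, df_inter, df_subj, df_resid],
            "F": [f_group, f_within, f_inter, np.nan, np.nan],
            "P": [p_group, p_within, p_inter, np.nan, np.nan],
            "percent_variation": [
                100 * s / ss_total
                for s in (ss_group, ss_within_factor, ss_inter, ss_subj, ss_resid)
            ],
        },
        index=pd.Index(
            ["between", "within", "interaction", "subject", "residual"],
            name="effect",
        ),
    )

    # Bonferroni post-hocs: between-group comparison at each within level,
    # pooled-variance t, adjusted P = min(1, n_levels * raw P) per pair.
    pairs = [
        (groups[i], groups[j]) for i in range(a) for j in range(i + 1, a)
    ]
    rows = []
    k = b  # the correction multiplies by the number of within levels
    for level in levels:
        sub = df[df[within] == level]
        for g1, g2 in pairs:
            x = sub.loc[sub[between] == g1, dv].to_numpy()
            y = sub.loc[sub[between] == g2, dv].to_numpy()
            t, p = stats.ttest_ind(x, y, equal_var=True)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if np.isclose(x.mean(), y.mean()) else 0.0
            rows.append(
                {
                    "level": level,
                    "group_1": g1,
                    "group_2": g2,
                    "mean_diff": x.mean() - y.mean(),
                    "t": t,
                    "p_raw": p,
                    "p_bonferroni": min(1.0, k * len(pairs) * p)
                    if len(pairs) > 1
                    else min(1.0, k * p),
                }
            )
    return AnovaResult(table=table, posthoc=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Unpaired t-test with Welch–Satterthwaite df. Returns (t, df, P).

    When both groups have zero variance and equal means, P = 1 by
    convention (no evidence of a difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def log_geomean_t_test(a, b) -> tuple[float, float, float, float, float]:
    """Student t-test on log-transformed observations.

    Returns (t, df, P, geomean_a, geomean_b). Appropriate for strictly
    positive, multiplicatively varying measurements (e.g. fluorescence
    geometric means); invariant to rescaling both groups by a constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ParameterError("log-scale test requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
        t, p = (0.0, 1.0) if np.isclose(la.mean(), lb.mean()) else (math.inf, 0.0)
    else:
        t, p = stats.ttest_ind(la, lb, equal_var=True)
    dof = float(a.size + b.size - 2)
    return float(t), dof, float(p), float(np.exp(la.mean())), float(np.exp(lb.mean()))


# ---------------------------------------------------------------------------
# Skew-normal frequency-distribution comparison
# ---------------------------------------------------------------------------


@dataclass
class DistComparison:
    """Extra-sum-of-squares F comparison of two fitted frequency
    distributions (pooled 3-parameter skew-normal vs one per group)."""

    ss_pooled: float
    ss_separate: float
    f: Optional[float]
    df1: int
    df2: int
    p: Optional[float]
    converged: bool


def _skewnorm_density(x: np.ndarray, shape: float, loc: float, scale: float) -> np.ndarray:
    return stats.skewnorm.pdf(x, shape, loc=loc, scale=scale)


def _fit_skewnorm_histograms(
    centers: np.ndarray, densities: list[np.ndarray], x0: np.ndarray
) -> tuple[float, np.ndarray, bool]:
    """Least-squares fit of one skew-normal density to >= 1 histograms
    sharing the (shape, loc, scale) parameters. Returns (SS, params, ok)."""

    def residuals(theta):
        shape, loc, log_scale = theta
        model = _skewnorm_density(centers, shape, loc, math.exp(log_scale))
        return np.concatenate([d - model for d in densities])

    sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=20_000)
    ss = float(2 * sol.cost)
    return ss, sol.x, bool(sol.success)


def compare_distributions_skewnormal(
    sample_a,
    sample_b,
    n_bins: int = 21,
) -> DistComparison:
    """Are two event-amplitude samples drawn from different distributions?

    Both samples are binned into normalised frequency distributions over a
    common range; a 3-parameter skew-normal (shape, location, scale) is
    least-squares fitted either pooled (one curve for both histograms) or
    separately (one per group). The extra-sum-of-squares F statistic has
    df1 = 3 (parameters freed) and df2 = total bins - 6; with the default
    21 bins per group this is F(3, 36).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ParameterError("need >= 10 events per sample to form histograms")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens_a = np.histogram(a, bins=edges, density=True)[0]
    dens_b = np.histogram(b, bins=edges, density=True)[0]

    pooled = np.concatenate([a, b])
    shape0, loc0, scale0 = stats.skewnorm.fit(pooled)
    x0 = np.array([shape0, loc0, math.log(max(scale0, 1e-9))])

    ss_pooled, theta_p, ok_p = _fit_skewnorm_histograms(
        centers, [dens_a, dens_b], x0
    )
    ss_a, _, ok_a = _fit_skewnorm_histograms(centers, [dens_a], theta_p)
    ss_b, _, ok_b = _fit_skewnorm_histograms(centers, [dens_b], theta_p)
    ss_sep = ss_a + ss_b
    converged = ok_p and ok_a and ok_b
    ss_sep = min(ss_sep, ss_pooled)  # nested models; guard fp round-off

    df1 = 3
    df2 = 2 * n_bins - 6
    if not converged or ss_sep <= 0 or df2 <= 0:
        return DistComparison(ss_pooled, ss_sep, None, df1, df2, None, converged)
    f = ((ss_pooled - ss_sep) / df1) / (ss_sep / df2)
    p = float(stats.f.sf(f, df1, df2))
    return DistComparison(ss_pooled, ss_sep, float(f), df1, df2, p, True)


def filter_events_by_rise_time(
    events: pd.DataFrame, max_rise_ms: float = 2.0, rise_column: str = "rise_ms"
) -> pd.DataFrame:
    """Drop events with a rise time slower than ``max_rise_ms`` (limits
    dendritic filtering artefacts before amplitude comparisons)."""
    if rise_column not in events.columns:
        raise ParameterError(f"events table lacks column {rise_column!r}")
    return events[events[rise_column] <= max_rise_ms].reset_index(drop=True)
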