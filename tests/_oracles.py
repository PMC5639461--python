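"""Independent brute-force oracles, deliberately written as plain loops so
they share no code path with the package implementations they check."""

from __future__ import annotations

import numpy as np


def sleep_flags_bruteforce(values, threshold_bins=4, onset="fourth_bin"):
    """Per-bin sleep flags by scanning immobile runs one bin at a time."""
    n = len(values)
    flags = [False] * n
    i = 0
    while i < n:
        if values[i] == 0:
            j = i
            while j < n and values[j] == 0:
                j += 1
            run = j - i
            if run >= threshold_bins:
                start = i + threshold_bins - 1 if onset == "fourth_bin" else i
                for k in range(start, j):
                    flags[k] = True
            i = j
        else:
            i += 1
    return np.array(flags)


def activity_bouts_bruteforce(values):
    """(start, length, intensity) of maximal active runs via a scan."""
    bouts = []
    n = len(values)
    i = 0
    while i < n:
        if values[i] > 0:
            j = i
            total = 0.0
            while j < n and values[j] > 0:
                total += values[j]
                j += 1
            bouts.append((i, j - i, total / (j - i)))
            i = j
        else:
            i += 1
    return bouts


def qp_bruteforce(series, period_bins):
    """Chi-square periodogram statistic by explicit column loops."""
    n = len(series)
    grand = sum(series) / n
    ss_tot = sum((x - grand) ** 2 for x in series)
    if ss_tot == 0:
        return 0.0
    num = 0.0
    for h in range(period_bins):
        col = [series[i] for i in range(h, n, period_bins)]
        m_h = sum(col) / len(col)
        num += len(col) * (m_h - grand) ** 2
    return n * num / ss_tot


def mixed_anova_ss_bruteforce(table):
    """Sums of squares for a balanced two-way mixed design by explicit
    mean decomposition. ``table[g][s][l]`` = value for group g, subject s,
    within-level l. Returns dict of SS terms."""
    values = [
        v
        for g in table
        for s in table[g]
        for v in table[g][s].values()
    ]
    grand = sum(values) / len(values)
    ss_total = sum((v - grand) ** 2 for v in values)

    levels = sorted({l for g in table for s in table[g] for l in table[g][s]})
    b = len(levels)

    group_mean = {
        g: np.mean([v for s in table[g] for v in table[g][s].values()])
        for g in table
    }
    subj_mean = {
        (g, s): np.mean(list(table[g][s].values()))
        for g in table
        for s in table[g]
    }
    level_mean = {
        l: np.mean([table[g][s][l] for g in table for s in table[g]])
        for l in levels
    }
    cell_mean = {
        (g, l): np.mean([table[g][s][l] for s in table[g]])
        for g in table
        for l in levels
    }

    ss_group = sum(
        b * len(table[g]) * (group_mean[g] - grand) ** 2 for g in table
    )
    ss_subj = sum(
        b * (subj_mean[(g, s)] - group_mean[g]) ** 2
        for g in table
        for s in table[g]
    )
    n_subjects = sum(len(table[g]) for g in table)
    ss_within = sum(n_subjects * (level_mean[l] - grand) ** 2 for l in levels)
    ss_inter = sum(
        len(table[g])
        * (cell_mean[(g, l)] - group_mean[g] - level_mean[l] + grand) ** 2
        for g in table
        for l in levels
    )
    ss_resid = ss_total - ss_group - ss_subj - ss_within - ss_inter
    return {
        "total": ss_total,
        "group": ss_group,
        "subject": ss_subj,
        "within": ss_within,
        "interaction": ss_inter,
        "residual": ss_resid,
    }
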