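"""Independent oracles used by the test suite.

These are deliberately written from the definitions (sorted scans, textbook
sums of squares) rather than reusing any code path from the package, so that
agreement is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(pvals):
    """Brute-force BH adjusted p-values from the step-up definition.

    Sort ascending; q for the i-th order statistic is the minimum over
    j >= i of p_(j) * m / j, capped at 1; map back to input order.
    """
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return np.array(q)


def classical_rm_anova(data: dict, groups, times):
    """Textbook two-way repeated-measures ANOVA (between = group, within = time).

    ``data`` maps (group, subject) -> array of responses over ``times``
    (balanced, complete).  Returns F statistics and the two error mean
    squares: (F_time, F_interaction, F_group, ms_within_error, ms_subject_error).
    """
    subj_of = {g: sorted({s for gg, s in data if gg == g}) for g in groups}
    T = len(times)
    n = {g: len(subj_of[g]) for g in groups}
    all_vals = np.array([data[k] for k in data])
    grand = all_vals.mean()
    gmean = {g: np.mean([data[(g, s)] for s in subj_of[g]]) for g in groups}
    gtmean = {g: np.mean([data[(g, s)] for s in subj_of[g]], axis=0) for g in groups}
    tmean = all_vals.mean(axis=0)  # equal n per group
    smean = {k: np.mean(v) for k, v in data.items()}

    N_subj = sum(n.values())
    ss_time = N_subj * np.sum((tmean - grand) ** 2)
    ss_group = T * sum(n[g] * (gmean[g] - grand) ** 2 for g in groups)
    ss_int = sum(
        n[g] * np.sum((gtmean[g] - gmean[g] - tmean + grand) ** 2) for g in groups
    )
    ss_subj = T * sum(
        (smean[(g, s)] - gmean[g]) ** 2 for g in groups for s in subj_of[g]
    )
    ss_err = sum(
        np.sum((data[(g, s)] - smean[(g, s)] - gtmean[g] + gmean[g]) ** 2)
        for g in groups
        for s in subj_of[g]
    )
    df_time = T - 1
    df_group = len(groups) - 1
    df_int = df_time * df_group
    df_subj = sum(n[g] - 1 for g in groups)
    df_err = df_subj * (T - 1)
    ms_w = ss_err / df_err
    ms_b = ss_subj / df_subj
    return (
        (ss_time / df_time) / ms_w,
        (ss_int / df_int) / ms_w,
        (ss_group / df_group) / ms_b,
        ms_w,
        ms_b,
    )
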