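"""Benjamini-Hochberg FDR, applied per statistical family across transcripts.

A "family" is one effect or one contrast column: adjustment runs down the
transcript axis within that column, never across columns, matching the
per-contrast FDR flags the reporting layer exposes.  Missing p-values
(non-converged transcripts) are excluded before adjustment, so the effective
family size m is the number of converged transcripts for that column.
"""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "apply_families"]

log = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), NaN entries passed through.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted non-missing p-values,
    capped at 1.  Raises ValueError for p outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    if mask.any():
        valid = flat[mask]
        if (valid < 0).any() or (valid > 1).any():
            bad = valid[(valid < 0) | (valid > 1)][0]
            raise ValueError(f"p-value {bad!r} outside [0, 1]")
    q = np.full(flat.shape, np.nan)
    if mask.any():
        q[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    return q.reshape(p.shape)


def apply_families(anova_result, alpha: float = 0.05):
    """Add a ``.q`` column next to every ``.p`` column of an AnovaTable.

    Returns a new :class:`~exanova.anova.AnovaResult`; the input is left
    untouched.  Columns whose p-values are all missing yield all-missing q
    columns (logged).
    """
    from .anova import AnovaResult  # local import to avoid a cycle

    table = anova_result.table.copy()
    new_cols: list[str] = []
    for col in table.columns:
        new_cols.append(col)
        if not col.endswith(".p"):
            continue
        qcol = col[:-2] + ".q"
        pvals = table[col].to_numpy()
        if np.isnan(pvals).all():
            log.warning("family %s: all p-values missing; q left missing", col)
        table[qcol] = bh_fdr(pvals)
        new_cols.append(qcol)
    table = table[new_cols]
    return AnovaResult(
        table=table,
        scheme=anova_result.scheme,
        spec=anova_result.spec,
        n_nonconverged=anova_result.n_nonconverged,
    )
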