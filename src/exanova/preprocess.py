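"""Baseline handling: per-subject Pre normalization and the Pre-only group check.

Changes over time are what matter in a paired design, so every sample is
expressed as its log2 difference from the same subject's own Pre sample
(equivalently, division of linear intensities).  A one-way fixed-effects
ANOVA on the Pre samples alone then checks for unintended baseline group
differences; with a clean randomization no transcript should clear FDR<0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .fdr import bh_fdr
from .io import ExpressionMatrix, StudyDesign, PRE_TIME

__all__ = ["RatioMatrix", "normalize_to_pre", "baseline_group_test", "BaselineReport"]

log = logging.getLogger(__name__)


@dataclass
class RatioMatrix:
    """Per-transcript log2 ratios to each subject's own Pre sample.

    Same shape and IDs as the source :class:`ExpressionMatrix`; every Pre
    column is exactly zero.
    """

    values: pd.DataFrame

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_to_pre(matrix, design: StudyDesign) -> RatioMatrix:
    """Subtract each subject's Pre column from all of that subject's samples.

    Accepts an :class:`ExpressionMatrix` or a :class:`RatioMatrix` (whose Pre
    columns are 0, making the operation idempotent).  Subject-level offsets
    cancel exactly, so adding any constant to all of one subject's samples
    leaves the result bit-for-bit unchanged.
    """
    vals = matrix.values
    design.validate_against_columns(vals.columns)
    unknown = set(vals.columns) - set(design.sample_ids)
    if unknown:
        raise DesignError(
            f"matrix sample {sorted(unknown)[0]!r} is absent from the design"
        )
    pre_of = design.pre_sample_of_subject()
    subj_of = design.table["subject_id"]
    ref_cols = [pre_of[subj_of[c]] for c in vals.columns]
    ratios = vals.to_numpy() - vals[ref_cols].to_numpy()
    return RatioMatrix(
        values=pd.DataFrame(ratios, index=vals.index, columns=vals.columns)
    )


@dataclass
class BaselineReport:
    """Pre-only one-way ANOVA across groups, BH-adjusted over transcripts."""

    table: pd.DataFrame  # columns F, p, q
    alpha: float

    @property
    def n_significant(self) -> int:
        return int((self.table["q"] < self.alpha).sum())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="transcript_id")


def baseline_group_test(
    matrix: ExpressionMatrix, design: StudyDesign, alpha: float = 0.05
) -> BaselineReport:
    """One-way fixed-effects ANOVA for group, on Pre samples only.

    Degenerate transcripts (zero within-group variance) get the conservative
    convention p = 1 when between-group variance is also zero; if groups are
    exactly separated with zero noise, F is infinite and p = 0.  The check is
    a gate, not an abort: a warning is logged when any transcript clears
    FDR < ``alpha``.
    """
    pre = design.table[design.table["time_h"] == PRE_TIME]
    group_arrays = []
    for g in design.groups:
        samples = pre.index[pre["group"] == g]
        if len(samples) < 2:
            raise DesignError(
                f"group {g!r} has {len(samples)} Pre sample(s); need >= 2"
            )
        group_arrays.append(matrix.values[list(samples)].to_numpy())
    if len(group_arrays) < 2:
        raise DesignError("baseline test needs at least 2 groups")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled below
        F, p = stats.f_oneway(*group_arrays, axis=1)

    # patch the zero-within-variance cases scipy leaves as NaN
    grand = np.concatenate(group_arrays, axis=1)
    ssw = sum(
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for a in group_arrays
    )
    means = np.column_stack([a.mean(axis=1) for a in group_arrays])
    sizes = np.array([a.shape[1] for a in group_arrays])
    ssb = (sizes * (means - grand.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    degenerate = ssw == 0
    flat = degenerate & (ssb == 0)
    F = np.where(degenerate, np.where(flat, 0.0, np.inf), F)
    p = np.where(degenerate, np.where(flat, 1.0, 0.0), p)

    q = bh_fdr(p)
    table = pd.DataFrame({"F": F, "p": p, "q": q}, index=matrix.values.index)
    report = BaselineReport(table=table, alpha=alpha)
    if report.n_significant:
        log.warning(
            "baseline Pre-only check: %d transcript(s) at FDR < %g suggest "
            "pre-existing group differences",
            report.n_significant,
            alpha,
        )
    return report
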