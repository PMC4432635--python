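"""End-to-end orchestration: normalize -> baseline gate -> ANOVA -> FDR -> rules."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anova import AnovaResult, ModelSpec, fit_all
from .classify import (
    ClassificationTable,
    CountReport,
    GroupRoles,
    build_count_report,
    classify_transcripts,
    infer_roles,
)
from .fdr import apply_families
from .io import ExpressionMatrix, StudyDesign
from .preprocess import BaselineReport, RatioMatrix, baseline_group_test, normalize_to_pre

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    ratios: RatioMatrix
    baseline: BaselineReport
    anova: AnovaResult
    classification: ClassificationTable
    counts: CountReport

    @property
    def roles(self) -> GroupRoles:
        return self.classification.roles


def run_pipeline(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    spec: ModelSpec | None = None,
    roles: GroupRoles | None = None,
    alpha: float = 0.05,
    p_interaction_floor: float = 0.1,
    p_vs_pre: float = 0.05,
    baseline_check: bool = True,
) -> PipelineResult:
    """Run the full analysis on a log2 expression matrix and its sample sheet.

    The baseline Pre-only check is a warning gate, not an abort; set
    ``baseline_check=False`` to skip it (e.g. on pre-normalized input).
    """
    design.validate_against(matrix)
    baseline = (
        baseline_group_test(matrix, design, alpha)
        if baseline_check
        else BaselineReport(table=pd.DataFrame(columns=["F", "p", "q"]), alpha=alpha)
    )
    ratios = normalize_to_pre(matrix, design)
    anova = fit_all(ratios, design, spec)
    anova = apply_families(anova, alpha)
    classification = classify_transcripts(
        anova,
        roles=roles or infer_roles(anova.scheme.groups),
        alpha=alpha,
        p_interaction_floor=p_interaction_floor,
        p_vs_pre=p_vs_pre,
    )
    counts = build_count_report(classification)
    return PipelineResult(
        ratios=ratios,
        baseline=baseline,
        anova=anova,
        classification=classification,
        counts=counts,
    )
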