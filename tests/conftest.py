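"""Shared fixtures: study-shaped designs and directly constructed ratio data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exanova import SimConfig, StudyDesign, generate_dataset

GROUPS = ("Control", "Endurance", "Resistance")
POST_TIMES = (2.5, 5.0)


def make_design(
    groups=GROUPS, n_subjects=6, times=(0.0, 2.5, 5.0)
) -> StudyDesign:
    """Balanced design in the shape of the emulated study."""
    rows = []
    for g in groups:
        for i in range(n_subjects):
            s = f"{g}{i + 1:02d}"
            for t in times:
                label = "Pre" if t == 0 else f"{t:g}h"
                rows.append((f"{s}_{label}", s, g, t))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "time_h"]
    ).set_index("sample_id")
    return StudyDesign(table=frame)


def make_ratio_rows(
    design: StudyDesign,
    n_transcripts: int,
    rng: np.random.Generator,
    sigma_subject: float = 0.5,
    sigma_noise: float = 0.25,
    cell_means: dict | None = None,
) -> pd.DataFrame:
    """Ratio-space data built directly: cell means + subject intercept + noise.

    Pre columns are exactly zero, mirroring the output of normalize_to_pre.
    """
    t = design.table
    subjects = design.subjects
    n_samples = len(t)
    y = np.zeros((n_transcripts, n_samples))
    is_post = (t["time_h"] != 0).to_numpy()
    subj_idx = np.array([subjects.index(s) for s in t["subject_id"]])
    for i in range(n_transcripts):
        b = rng.normal(0.0, sigma_subject, len(subjects))
        row = b[subj_idx] + rng.normal(0.0, sigma_noise, n_samples)
        if cell_means:
            for j, (g, tp) in enumerate(zip(t["group"], t["time_h"])):
                row[j] += cell_means.get((i, g, tp), 0.0)
        y[i] = np.where(is_post, row, 0.0)
    return pd.DataFrame(
        y, index=[f"R{i + 1:04d}" for i in range(n_transcripts)], columns=t.index
    )


@pytest.fixture(scope="session")
def study_design() -> StudyDesign:
    return make_design()


@pytest.fixture(scope="session")
def small_dataset():
    """300-transcript simulated dataset with planted effects (seeded)."""
    cfg = SimConfig(
        n_transcripts=300,
        seed=2024,
        class_proportions={
            "null": 0.7,
            "specific:Endurance": 0.1,
            "general_independent": 0.1,
            "time_all_groups": 0.1,
        },
    )
    return generate_dataset(cfg)
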