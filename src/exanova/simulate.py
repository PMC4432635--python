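"""Planted-effect simulator for subject-paired, multi-group time-course expression.

Emulates the structure of a three-arm exercise study (control, endurance,
resistance), each subject sampled at a baseline biopsy (Pre) and two
post-intervention recovery times.  Raw log2 intensities are

    value[transcript, sample] = baseline[transcript]
                               + subject_intercept[transcript, subject]
                               + planted_shift(group, time)
                               + noise

with Gaussian noise on the log2 scale (log-normal raw intensities) and one
random intercept per subject shared across that subject's time points —
exactly the structure a repeated-measures REML ANOVA assumes.  Planted shifts
never touch Pre samples, so every effect is a true change from baseline.

Effect classes
--------------
``null``                  no shift anywhere.
``specific:<group>``      shift in that group's post cells only.
``general_independent``   equal shift in every exercise group's post cells.
``general_dependent``     opposite-sign shifts in the two exercise groups.
``time_all_groups``       equal shift in every group's post cells (a
                          time-of-day / dietary style effect that also moves
                          the non-exercise controls).

RNG draw order (one seeded generator): per-transcript baselines, then subject
intercepts (transcript-major), then residual noise (transcript-major).  Class
assignment is deterministic (largest-remainder apportionment over contiguous
transcript blocks) and consumes no randomness, so identical configs give
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, StudyDesign, PRE_TIME

__all__ = ["SimConfig", "TruthTable", "plant_effect", "generate_dataset"]

DEFAULT_GROUPS = ("Control", "Endurance", "Resistance")
DEFAULT_TIMES = (0.0, 2.5, 5.0)


def default_class_proportions(groups=DEFAULT_GROUPS) -> dict[str, float]:
    exercise = list(groups[1:])
    props = {"null": 0.90}
    for g in exercise[:2]:
        props[f"specific:{g}"] = 0.02
    props["general_independent"] = 0.02
    props["general_dependent"] = 0.02
    props["time_all_groups"] = 1.0 - sum(props.values())
    return props


def time_label(t: float) -> str:
    return "Pre" if t == PRE_TIME else f"{t:g}h"


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the study design being emulated
    (3 groups x 6 subjects x 3 time points, log2-scale Gaussian noise)."""

    n_transcripts: int = 1000
    n_subjects_per_group: int = 6
    groups: tuple[str, ...] = DEFAULT_GROUPS
    times_h: tuple[float, ...] = DEFAULT_TIMES
    sigma_noise: float = 0.25
    sigma_subject: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    class_proportions: dict[str, float] | None = None
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = default_class_proportions(self.groups)
        self.validate()

    @property
    def control_group(self) -> str:
        """First group whose label reads 'control', else the first group."""
        for g in self.groups:
            if g.lower() == "control":
                return g
        return self.groups[0]

    @property
    def exercise_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.control_group)

    def validate(self) -> None:
        if not (isinstance(self.n_transcripts, (int, np.integer)) and self.n_transcripts > 0):
            raise ConfigError("n_transcripts must be a positive integer")
        if not (isinstance(self.n_subjects_per_group, (int, np.integer))
                and self.n_subjects_per_group > 0):
            raise ConfigError("n_subjects_per_group must be a positive integer")
        if len(self.groups) < 2:
            raise ConfigError("groups must list at least 2 group labels")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups contains duplicate labels")
        if PRE_TIME not in self.times_h:
            raise ConfigError("times_h must include the Pre level (0)")
        if len(set(self.times_h)) != len(self.times_h):
            raise ConfigError("times_h contains duplicate time points")
        for name in ("sigma_noise", "sigma_subject", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigError("class_proportions must be non-negative")
        for label in self.class_proportions:
            # raises ConfigError on unknown labels
            plant_effect(label, self.effect_size, self.groups, self.times_h,
                         control_group=self.control_group)


def plant_effect(
    class_label: str,
    effect_size: float,
    groups,
    times_h,
    control_group: str | None = None,
) -> dict[tuple[str, float], float]:
    """Return the (group, time) -> log2 shift pattern for one effect class.

    Pre cells are never shifted; control cells are shifted only by
    ``time_all_groups``.
    """
    groups = tuple(groups)
    if control_group is None:
        control_group = next(
            (g for g in groups if g.lower() == "control"), groups[0]
        )
    exercise = [g for g in groups if g != control_group]
    post = [t for t in times_h if t != PRE_TIME]

    if class_label == "null":
        return {}
    if class_label.startswith("specific:"):
        g = class_label.split(":", 1)[1]
        if g not in groups:
            raise ConfigError(f"unknown group {g!r} in class label {class_label!r}")
        return {(g, t): effect_size for t in post}
    if class_label == "general_independent":
        return {(g, t): effect_size for g in exercise for t in post}
    if class_label == "general_dependent":
        if len(exercise) < 2:
            raise ConfigError(
                "general_dependent needs at least two exercise groups"
            )
        signs = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(exercise)}
        return {(g, t): signs[g] * effect_size for g in exercise for t in post}
    if class_label == "time_all_groups":
        return {(g, t): effect_size for g in groups for t in post}
    raise ConfigError(f"unknown effect class label {class_label!r}")


@dataclass
class TruthTable:
    """Planted-effect bookkeeping for scoring downstream calls.

    ``table`` has one row per transcript (``planted_class``); ``affected``
    maps transcript_id -> {(group, time): log2 shift}.
    """

    table: pd.DataFrame
    affected: dict[str, dict[tuple[str, float], float]]

    def transcripts_of_class(self, class_label: str) -> list[str]:
        mask = self.table["planted_class"] == class_label
        return list(self.table.index[mask])

    def write(self, path) -> None:
        out = self.table.copy()
        out["affected_cells"] = [
            json.dumps(
                [[g, t, s] for (g, t), s in sorted(self.affected[tid].items())]
            )
            for tid in out.index
        ]
        out.to_csv(path, sep="\t", index_label="transcript_id")


def _apportion(proportions: dict[str, float], n: int) -> list[tuple[str, int]]:
    """Largest-remainder apportionment of n transcripts over classes."""
    items = list(proportions.items())
    raw = [p * n for _, p in items]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(items)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return [(label, c) for (label, _), c in zip(items, counts)]


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, StudyDesign, TruthTable]:
    """Simulate a full dataset: expression matrix, sample sheet, truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = list(config.groups)
    times = list(config.times_h)
    n_per = config.n_subjects_per_group
    subjects = [f"{g}{i + 1:02d}" for g in groups for i in range(n_per)]
    subj_group = {s: g for g, s in zip(np.repeat(groups, n_per), subjects)}

    rows = []
    for s in subjects:
        for t in times:
            rows.append((f"{s}_{time_label(t)}", s, subj_group[s], t))
    design_df = pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "group", "time_h"]
    ).set_index("sample_id")
    design = StudyDesign(table=design_df)

    n_tr = config.n_transcripts
    width = max(6, len(str(n_tr)))
    transcript_ids = [f"T{i:0{width}d}" for i in range(1, n_tr + 1)]

    # deterministic class assignment: contiguous blocks, largest remainder
    classes: list[str] = []
    for label, count in _apportion(config.class_proportions, n_tr):
        classes.extend([label] * count)

    affected = {
        tid: plant_effect(cls, config.effect_size, groups, times,
                          control_group=config.control_group)
        for tid, cls in zip(transcript_ids, classes)
    }

    # documented draw order: baselines, subject intercepts, residual noise
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_tr)
    subj_int = rng.normal(0.0, config.sigma_subject, (n_tr, len(subjects)))
    n_samples = len(design_df)
    noise = rng.normal(0.0, config.sigma_noise, (n_tr, n_samples))

    subj_index = {s: k for k, s in enumerate(subjects)}
    col_subj = np.array([subj_index[s] for s in design_df["subject_id"]])

    shift = np.zeros((n_tr, n_samples))
    cell_cols: dict[tuple[str, float], np.ndarray] = {}
    for g in groups:
        for t in times:
            mask = (design_df["group"] == g) & (design_df["time_h"] == t)
            cell_cols[(g, t)] = np.flatnonzero(mask.to_numpy())
    for i, tid in enumerate(transcript_ids):
        for cell, delta in affected[tid].items():
            shift[i, cell_cols[cell]] += delta

    values = baseline[:, None] + subj_int[:, col_subj] + shift + noise
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=transcript_ids,
                            columns=design_df.index)
    )
    truth = TruthTable(
        table=pd.DataFrame({"planted_class": classes}, index=transcript_ids),
        affected=affected,
    )
    return matrix, design, truth


def write_dataset(matrix, design, truth, out_dir) -> dict[str, Path]:
    """Write the three simulation outputs as TSV under ``out_dir``."""
    from .io import write_design, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(matrix, paths["expression"])
    write_design(design, paths["design"])
    truth.write(paths["truth"])
    return paths
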