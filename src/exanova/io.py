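"""Core data containers and TSV/CSV readers/writers.

The pipeline works on log2-scale expression values (e.g. RMA summaries of
Affymetrix Gene ST arrays): a transcripts x samples matrix, a sample sheet
mapping each sample to a subject, a group and a time point, and an optional
transcript -> gene-symbol annotation.  Files are plain UTF-8 tables with a
header row; the delimiter is inferred from the extension (``.csv`` -> comma,
anything else -> tab).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_annotation",
    "join_annotation",
]

PRE_TIME = 0.0


def _delimiter(path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Transcripts x samples matrix of log2 intensities.

    ``values`` is a DataFrame indexed by transcript ID with one column per
    sample.  ``gene_symbols`` (optional) maps transcript IDs to symbols; the
    empty string means "no annotation".
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ParseError(f"duplicate transcript_id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ParseError(f"duplicate sample_id {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = map(int, np.argwhere(~np.isfinite(arr))[0])
            raise ParseError(
                f"non-finite value at transcript {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(idx).fillna("")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class StudyDesign:
    """Sample sheet: one row per sample with subject, group and time (hours).

    Pre (baseline) samples are encoded as ``time_h == 0``.  Construction
    validates that every subject sits in exactly one group and owns exactly
    one Pre sample.
    """

    table: pd.DataFrame  # index sample_id; columns subject_id, group, time_h

    def __post_init__(self) -> None:
        t = self.table
        required = {"subject_id", "group", "time_h"}
        missing = required - set(t.columns)
        if missing:
            raise ParseError(f"design is missing columns {sorted(missing)}")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise DesignError(f"duplicate sample_id {dup!r}")
        groups_per_subject = t.groupby("subject_id")["group"].nunique()
        bad = groups_per_subject[groups_per_subject > 1]
        if len(bad):
            raise DesignError(
                f"subject {bad.index[0]!r} appears in more than one group"
            )
        pre_counts = (
            t[t["time_h"] == PRE_TIME].groupby("subject_id").size().reindex(
                t["subject_id"].unique(), fill_value=0
            )
        )
        bad = pre_counts[pre_counts != 1]
        if len(bad):
            raise DesignError(
                f"subject {bad.index[0]!r} has {int(bad.iloc[0])} Pre samples "
                "(exactly one required)"
            )

    # -- derived views -----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.table["group"]))

    @property
    def times(self) -> list[float]:
        return sorted(self.table["time_h"].unique())

    @property
    def post_times(self) -> list[float]:
        return [t for t in self.times if t != PRE_TIME]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))

    def group_of_subject(self) -> pd.Series:
        return self.table.groupby("subject_id", sort=False)["group"].first()

    def subjects_in_group(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        return list(dict.fromkeys(sub["subject_id"]))

    def pre_sample_of_subject(self) -> dict[str, str]:
        pre = self.table[self.table["time_h"] == PRE_TIME]
        return {row.subject_id: idx for idx, row in pre.iterrows()}

    @property
    def completeness(self) -> pd.DataFrame:
        """Boolean subject x time table: does the subject have that sample?"""
        counts = self.table.groupby(["subject_id", "time_h"]).size().unstack(
            fill_value=0
        )
        return counts.reindex(
            index=self.subjects, columns=self.times, fill_value=0
        ) == 1

    @property
    def is_balanced(self) -> bool:
        """Complete (every subject at every time, once) with equal group sizes."""
        if not self.completeness.to_numpy().all():
            return False
        sizes = {len(self.subjects_in_group(g)) for g in self.groups}
        return len(sizes) == 1

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        self.validate_against_columns(matrix.sample_ids)

    def validate_against_columns(self, columns) -> None:
        missing = set(self.sample_ids) - set(columns)
        if missing:
            raise DesignError(
                f"design sample {sorted(missing)[0]!r} not present in the matrix"
            )


# -- expression matrix I/O -------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read a transcripts x samples table (first column = transcript IDs)."""
    path = Path(path)
    delim = _delimiter(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delim)
    sample_ids = header[1:]
    seen: set[str] = set()
    for j, s in enumerate(sample_ids):
        if s in seen:
            raise ParseError(f"duplicate sample column {s!r} (column {j + 2})")
        seen.add(s)
    try:
        # round_trip parsing keeps read(write(x)) exact, not just close
        df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path.name}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        row = int(np.flatnonzero(df.index == dup)[-1]) + 2
        raise ParseError(f"duplicate transcript_id {dup!r} (row {row})")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric or missing value at row {i + 2}, "
            f"column {df.columns[j]!r} (transcript {df.index[i]!r})"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(values=numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    delim = _delimiter(path)
    matrix.values.to_csv(path, sep=delim, index_label="transcript_id")


# -- study design I/O ------------------------------------------------------


def _parse_time(value) -> float:
    """Map a time cell to hours; 'Pre' (any case) is the baseline, 0 h."""
    if isinstance(value, str) and value.strip().lower() == "pre":
        return PRE_TIME
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"unparseable time value {value!r}") from None


def read_design(path) -> StudyDesign:
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    required = ["sample_id", "subject_id", "group", "time_h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"design file missing columns {missing}")
    df["time_h"] = [_parse_time(v) for v in df["time_h"]]
    df = df.set_index("sample_id")
    return StudyDesign(table=df[["subject_id", "group", "time_h"]])


def write_design(design: StudyDesign, path) -> None:
    out = design.table.copy()
    out.to_csv(path, sep=_delimiter(path), index_label="sample_id")


# -- annotation ------------------------------------------------------------


def read_annotation(path) -> pd.Series:
    """Read a transcript_id -> gene_symbol table as a Series."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    if df.shape[1] < 2:
        raise ParseError("annotation needs transcript_id and gene_symbol columns")
    ids, symbols = df.iloc[:, 0], df.iloc[:, 1].fillna("")
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ParseError(f"duplicate transcript_id {dup!r} in annotation")
    return pd.Series(symbols.to_numpy(), index=ids.to_numpy(), name="gene_symbol")


def join_annotation(matrix: ExpressionMatrix, annotation: pd.Series) -> ExpressionMatrix:
    """Attach gene symbols where transcript IDs match; unmatched stay empty."""
    symbols = annotation.reindex(matrix.values.index).fillna("")
    return ExpressionMatrix(values=matrix.values, gene_symbols=symbols)
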