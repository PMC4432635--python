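"""Per-gene summaries, queries and workbook-style exports.

The access layer mirrors a "simplified data access" spreadsheet: per
transcript and group x time cell, the geometric mean fold change with a
back-transformed s.e.m. band (mean +/- SEM on the log2 scale, then
exponentiated), per-subject trajectories, and the statistical flags.  A
query by gene symbol returns this bundle for every matching transcript, and
``export_workbook`` writes the whole dataset as deterministic TSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import AnovaResult, _tlabel
from .classify import ClassificationTable
from .io import PRE_TIME, StudyDesign
from .preprocess import RatioMatrix

__all__ = ["geo_mean_sem", "GeneSummary", "query_gene", "export_workbook", "plot_gene"]

log = logging.getLogger(__name__)


def geo_mean_sem(log2_values) -> tuple[float, float, float]:
    """Geometric mean and back-transformed s.e.m. band of log2 fold changes.

    With m the arithmetic mean of the log2 values and s their standard error
    (sample SD / sqrt(n); 0 when n = 1), returns (2**m, 2**(m-s), 2**(m+s)).
    The band is symmetric on the log scale by construction.
    """
    arr = np.asarray(log2_values, dtype=float)
    if arr.size == 0:
        raise ValueError("geo_mean_sem needs at least one value")
    if not np.isfinite(arr).all():
        raise ValueError("geo_mean_sem requires finite values")
    m = arr.mean()
    s = 0.0 if arr.size == 1 else arr.std(ddof=1) / np.sqrt(arr.size)
    return (2.0**m, 2.0 ** (m - s), 2.0 ** (m + s))


@dataclass
class GeneSummary:
    """Everything the access layer knows about one transcript."""

    transcript_id: str
    symbol: str
    #: per (group, time) row: geo_mean, band_low, band_high (fold scale)
    means: pd.DataFrame
    #: per-subject log2 ratios: subject_id, group, time_h, log2_ratio
    individual: pd.DataFrame
    #: contrast/effect statistics for this transcript (the AnovaTable row)
    stats: pd.Series
    #: classification flags for this transcript
    classification: pd.Series
    #: names of contrasts significant at the FDR threshold
    significant_flags: list[str]


def _cell_values(ratios: RatioMatrix, design: StudyDesign, tid: str) -> pd.DataFrame:
    row = ratios.values.loc[tid]
    t = design.table
    out = pd.DataFrame(
        {
            "subject_id": t["subject_id"].to_numpy(),
            "group": t["group"].to_numpy(),
            "time_h": t["time_h"].to_numpy(),
            "log2_ratio": row[t.index].to_numpy(),
        }
    )
    return out.sort_values(["group", "subject_id", "time_h"], kind="stable").reset_index(
        drop=True
    )


def summarize_transcript(
    tid: str,
    ratios: RatioMatrix,
    design: StudyDesign,
    anova: AnovaResult,
    classification: ClassificationTable,
    symbol: str = "",
    alpha: float = 0.05,
) -> GeneSummary:
    indiv = _cell_values(ratios, design, tid)
    rows = []
    for g in design.groups:
        for t in design.times:
            vals = indiv.query("group == @g and time_h == @t")["log2_ratio"]
            if len(vals) == 0:
                continue
            gm, lo, hi = geo_mean_sem(vals.to_numpy())
            rows.append((g, t, gm, lo, hi))
    means = pd.DataFrame(
        rows, columns=["group", "time_h", "geo_mean", "band_low", "band_high"]
    ).set_index(["group", "time_h"])

    stats_row = anova.table.loc[tid]
    flags = [
        col[: -len(".q")]
        for col in anova.table.columns
        if col.endswith(".q") and pd.notna(stats_row[col]) and stats_row[col] < alpha
    ]
    return GeneSummary(
        transcript_id=tid,
        symbol=symbol,
        means=means,
        individual=indiv,
        stats=stats_row,
        classification=classification.frame.loc[tid],
        significant_flags=flags,
    )


def query_gene(
    symbol: str,
    ratios: RatioMatrix,
    design: StudyDesign,
    anova: AnovaResult,
    classification: ClassificationTable,
    annotation: pd.Series,
    alpha: float = 0.05,
) -> list[GeneSummary]:
    """All transcripts annotated with ``symbol`` (exact, case-insensitive).

    An unknown symbol returns an empty list (and logs the miss) rather than
    raising, mirroring an empty spreadsheet lookup.
    """
    wanted = symbol.strip().lower()
    matches = [
        tid
        for tid, sym in annotation.items()
        if isinstance(sym, str) and sym.lower() == wanted and tid in anova.table.index
    ]
    if not matches:
        log.info("gene symbol %r not found in the annotation", symbol)
        return []
    return [
        summarize_transcript(
            tid, ratios, design, anova, classification,
            symbol=str(annotation[tid]), alpha=alpha,
        )
        for tid in matches
    ]


# ---------------------------------------------------------------------------
# Workbook-style export
# ---------------------------------------------------------------------------

_INSTRUCTIONS = """\
Workbook export
===============

Files
-----
stats_and_means.tsv   one row per transcript: gene symbol, every effect and
                      contrast statistic (estimate / SE / raw p / BH q),
                      classification labels, and the geometric-mean fold
                      change per group x time cell (columns geomean.<cell>).
individual_data.tsv   one row per transcript x sample: the subject's log2
                      ratio to their own Pre biopsy.
manifest.yaml         thresholds and versions used to produce this export.

Usage
-----
Filter stats_and_means.tsv on a statistical column to list regulated
transcripts (e.g. specific_label == <group>), or filter on gene_symbol to
inspect one gene; individual_data.tsv carries the per-subject trajectories
behind each summary.  All fold changes are linear scale; their logs are the
mean log2 ratios, so error bands are symmetric on a log axis.
"""


def export_workbook(
    ratios: RatioMatrix,
    design: StudyDesign,
    anova: AnovaResult,
    classification: ClassificationTable,
    annotation: pd.Series | None,
    out_dir,
    alpha: float = 0.05,
) -> dict[str, Path]:
    """Write the spreadsheet-equivalent TSV set; deterministic for fixed inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ids = list(anova.table.index)
    symbols = (
        annotation.reindex(ids).fillna("")
        if annotation is not None
        else pd.Series("", index=ids)
    )

    stats = pd.DataFrame(index=pd.Index(ids, name="transcript_id"))
    stats["gene_symbol"] = symbols.to_numpy()
    for col in anova.table.columns:
        stats[col] = anova.table[col]
    label_cols = ["specific_label", "general_label", "time_regulated"]
    for col in label_cols:
        stats[col] = classification.frame[col]

    # geometric means per cell, vectorized over transcripts
    t = design.table
    for g in design.groups:
        for time in design.times:
            cols = t.index[(t["group"] == g) & (t["time_h"] == time)]
            block = ratios.values[list(cols)].to_numpy()
            stats[f"geomean.{g}.{_time_name(time)}"] = 2.0 ** block.mean(axis=1)

    paths = {
        "instructions": out / "instructions.txt",
        "stats": out / "stats_and_means.tsv",
        "individual": out / "individual_data.tsv",
        "manifest": out / "manifest.yaml",
    }
    paths["instructions"].write_text(_INSTRUCTIONS, encoding="utf-8")
    stats.to_csv(paths["stats"], sep="\t")

    long = ratios.values.stack()
    long.index.names = ["transcript_id", "sample_id"]
    long = long.rename("log2_ratio").reset_index()
    meta = design.table.reset_index().rename(columns={"index": "sample_id"})
    long = long.merge(meta, on="sample_id", how="left")
    long["gene_symbol"] = symbols.reindex(long["transcript_id"]).to_numpy()
    long = long[
        ["transcript_id", "gene_symbol", "subject_id", "group", "time_h", "log2_ratio"]
    ]
    long.to_csv(paths["individual"], sep="\t", index=False)

    from . import __version__

    manifest = {
        "exanova_version": __version__,
        "alpha_fdr": float(alpha),
        "thresholds": {k: float(v) for k, v in classification.thresholds.items()},
        "n_transcripts": int(len(ids)),
        "n_samples": int(len(design.table)),
        "groups": [str(g) for g in design.groups],
        "times_h": [float(x) for x in design.times],
        "files": sorted(str(p.name) for p in paths.values()),
    }
    paths["manifest"].write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return paths


def _time_name(t: float) -> str:
    return "Pre" if t == PRE_TIME else _tlabel(t)


def plot_gene(summary: GeneSummary, path) -> None:
    """Bar panel of fold changes with s.e.m. bands plus per-subject dot panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = summary.means.reset_index()
    groups = list(dict.fromkeys(means["group"]))
    times = sorted(means["time_h"].unique())
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))

    width = 0.8 / len(groups)
    for k, g in enumerate(groups):
        sub = means[means["group"] == g].set_index("time_h").reindex(times)
        x = np.arange(len(times)) + k * width
        yerr = np.vstack(
            [
                sub["geo_mean"] - sub["band_low"],
                sub["band_high"] - sub["geo_mean"],
            ]
        )
        ax1.bar(x, sub["geo_mean"], width=width, label=g, yerr=yerr, capsize=2)
    ax1.set_yscale("log", base=2)
    ax1.axhline(1.0, color="k", lw=0.5)
    ax1.set_xticks(np.arange(len(times)) + 0.4 - width / 2)
    ax1.set_xticklabels([_time_name(t) for t in times])
    ax1.set_ylabel("fold change vs Pre (log2 axis)")
    ax1.set_title(f"{summary.symbol or summary.transcript_id} - geometric mean ± s.e.m.")
    ax1.legend(fontsize=8)

    for g in groups:
        sub = summary.individual[summary.individual["group"] == g]
        for subj, traj in sub.groupby("subject_id"):
            traj = traj.sort_values("time_h")
            ax2.plot(traj["time_h"], 2.0 ** traj["log2_ratio"], "o-", alpha=0.5, lw=0.8)
    ax2.set_yscale("log", base=2)
    ax2.axhline(1.0, color="k", lw=0.5)
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("fold change vs Pre (log2 axis)")
    ax2.set_title("individual subjects")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
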