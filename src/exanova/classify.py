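"""Rule-based classification of transcripts from the q/p table.

Implements the study's explicit rule sets on top of the per-contrast FDR
q-values and raw p-values:

* changed versus Pre, per group x time (q < alpha);
* changed between groups, per pair x time (q < alpha);
* group-specific: significantly different from Pre and from BOTH other
  groups at at least one post time, and never different from Pre in any
  other group;
* exercise-general: changed versus Pre in both exercise groups, split into
  "independent of exercise type" (no significant between-exercise contrast)
  and "dependent of exercise type" (a significant between-exercise contrast
  at some post time);
* time-regulated: marginal change from Pre at a post time (FDR < alpha on
  the across-group time contrast), no interaction signal (raw p > 0.1), and
  all groups individually changed from Pre (raw p < 0.05) at that same time.

Clauses that the source rules state on the raw-p scale use raw p; everything
else uses BH q < alpha.  The rule engine is a pure function of the table:
identical inputs classify identically regardless of order.  Non-converged
transcripts are left unlabelled and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import AnovaResult, ContrastScheme, _tlabel
from .errors import ConfigError

__all__ = [
    "GroupRoles",
    "infer_roles",
    "changed_vs_pre",
    "changed_between_groups",
    "group_specific",
    "exercise_general",
    "time_regulated",
    "classify_transcripts",
    "ClassificationTable",
    "CountReport",
    "build_count_report",
]

NONE_LABEL = "none"


@dataclass(frozen=True)
class GroupRoles:
    """Which group is the non-exercise control; the rest are exercise arms."""

    control: str
    exercise: tuple[str, ...]


def infer_roles(groups) -> GroupRoles:
    """Control = the group labelled 'control' (case-insensitive), else the first."""
    groups = list(groups)
    control = next((g for g in groups if g.lower() == "control"), groups[0])
    return GroupRoles(control=control, exercise=tuple(g for g in groups if g != control))


def _require(anova: AnovaResult, column: str) -> pd.Series:
    if column not in anova.table.columns:
        raise ConfigError(f"AnovaTable is missing required column {column!r}")
    return anova.table[column]


def changed_vs_pre(anova: AnovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean table: q of the group-at-time-vs-Pre contrast < alpha.

    Columns are a (group, time) MultiIndex; missing q (non-converged) counts
    as not changed.
    """
    scheme = anova.scheme
    data = {}
    for g in scheme.groups:
        for t in scheme.post_times:
            q = _require(anova, f"{scheme.vs_pre_name(g, t)}.q")
            data[(g, t)] = (q < alpha).fillna(False).to_numpy()
    out = pd.DataFrame(data, index=anova.table.index)
    out.columns = pd.MultiIndex.from_tuples(data.keys(), names=["group", "time_h"])
    return out


def changed_between_groups(anova: AnovaResult, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean table for pairwise group contrasts: q < alpha per (g1, g2, time)."""
    scheme = anova.scheme
    data = {}
    for a, b in scheme.pairs:
        for t in scheme.post_times:
            q = _require(anova, f"{scheme.pair_name(a, b, t)}.q")
            data[(a, b, t)] = (q < alpha).fillna(False).to_numpy()
    out = pd.DataFrame(data, index=anova.table.index)
    out.columns = pd.MultiIndex.from_tuples(
        data.keys(), names=["group1", "group2", "time_h"]
    )
    return out


def _pair_flags(between: pd.DataFrame, g1: str, g2: str) -> pd.DataFrame:
    """Per-time flags for an unordered group pair."""
    cols = between.columns
    for a, b in ((g1, g2), (g2, g1)):
        sel = [c for c in cols if c[0] == a and c[1] == b]
        if sel:
            return between[sel]
    raise ConfigError(f"no between-group contrast for pair ({g1!r}, {g2!r})")


def group_specific(
    changed_pre: pd.DataFrame, changed_between: pd.DataFrame
) -> pd.Series:
    """Label transcripts responsive to exactly one group.

    A transcript is specific to group g when, at some post time, it is
    changed versus Pre in g AND different from both other groups, and it is
    never changed versus Pre in any other group at any time.  At most one
    group can satisfy this, so labels are single-valued by construction.
    """
    groups = list(dict.fromkeys(changed_pre.columns.get_level_values(0)))
    times = list(dict.fromkeys(changed_pre.columns.get_level_values(1)))
    labels = pd.Series(NONE_LABEL, index=changed_pre.index, dtype=object)
    for g in groups:
        others = [o for o in groups if o != g]
        hit_any_time = pd.Series(False, index=changed_pre.index)
        for t in times:
            hit = changed_pre[(g, t)].copy()
            for o in others:
                pair_t = _pair_flags(changed_between, g, o)
                col = [c for c in pair_t.columns if c[2] == t]
                hit &= pair_t[col[0]]
            hit_any_time |= hit
        unchanged_elsewhere = pd.Series(True, index=changed_pre.index)
        for o in others:
            for t in times:
                unchanged_elsewhere &= ~changed_pre[(o, t)]
        labels[hit_any_time & unchanged_elsewhere] = g
    return labels


def exercise_general(
    changed_pre: pd.DataFrame,
    changed_between: pd.DataFrame,
    roles: GroupRoles,
) -> pd.Series:
    """Label transcripts changed in every exercise group.

    "independent" = no significant between-exercise contrast at any post
    time; "dependent" = the exercise arms differ from each other at some
    post time.  The two labels are disjoint by construction.
    """
    times = list(dict.fromkeys(changed_pre.columns.get_level_values(1)))
    candidate = pd.Series(True, index=changed_pre.index)
    for e in roles.exercise:
        changed_somewhere = pd.Series(False, index=changed_pre.index)
        for t in times:
            changed_somewhere |= changed_pre[(e, t)]
        candidate &= changed_somewhere
    differ = pd.Series(False, index=changed_pre.index)
    for i in range(1, len(roles.exercise)):
        for j in range(i):
            pair = _pair_flags(
                changed_between, roles.exercise[i], roles.exercise[j]
            )
            differ |= pair.any(axis=1)
    labels = pd.Series(NONE_LABEL, index=changed_pre.index, dtype=object)
    labels[candidate & differ] = "dependent"
    labels[candidate & ~differ] = "independent"
    return labels


def time_regulated(
    anova: AnovaResult,
    alpha_fdr: float = 0.05,
    p_interaction_floor: float = 0.1,
    p_vs_pre: float = 0.05,
) -> pd.DataFrame:
    """Flag transcripts regulated by time alone (in all groups, no interaction).

    flag(t) = raw interaction p > ``p_interaction_floor``
              AND marginal time-vs-Pre q at t < ``alpha_fdr``
              AND every group's raw vs-Pre p at t < ``p_vs_pre``.
    Returns one boolean column per post time plus an ``any`` column.
    """
    scheme = anova.scheme
    # the interaction of the factorial model with its baseline level: groups
    # differing in change-from-Pre at any post time is an interaction signal
    p_int = _require(anova, "TimexGroupVsPre.p")
    no_interaction = (p_int > p_interaction_floor).fillna(False)
    out = {}
    any_time = pd.Series(False, index=anova.table.index)
    for t in scheme.post_times:
        q_time = _require(anova, f"{scheme.marginal_name(t)}.q")
        flag = no_interaction & (q_time < alpha_fdr).fillna(False)
        for g in scheme.groups:
            p_g = _require(anova, f"{scheme.vs_pre_name(g, t)}.p")
            flag &= (p_g < p_vs_pre).fillna(False)
        out[_tlabel(t)] = flag
        any_time |= flag
    out["any"] = any_time
    return pd.DataFrame(out, index=anova.table.index)


# ---------------------------------------------------------------------------
# Orchestration and counting
# ---------------------------------------------------------------------------


@dataclass
class ClassificationTable:
    """Per-transcript flags and labels, with the thresholds that produced them."""

    frame: pd.DataFrame
    scheme: ContrastScheme
    roles: GroupRoles
    thresholds: dict[str, float]

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in sorted(self.thresholds.items()):
                fh.write(f"# {key} = {val:g}\n")
            self.frame.to_csv(fh, sep="\t", index_label="transcript_id")


def classify_transcripts(
    anova: AnovaResult,
    roles: GroupRoles | None = None,
    alpha: float = 0.05,
    p_interaction_floor: float = 0.1,
    p_vs_pre: float = 0.05,
) -> ClassificationTable:
    """Run every rule set; non-converged transcripts stay unlabelled."""
    scheme = anova.scheme
    if roles is None:
        roles = infer_roles(scheme.groups)
    chg = changed_vs_pre(anova, alpha)
    btw = changed_between_groups(anova, alpha)
    specific = group_specific(chg, btw)
    general = exercise_general(chg, btw, roles)
    timereg = time_regulated(anova, alpha, p_interaction_floor, p_vs_pre)

    converged = anova.table["converged"].astype(bool)
    frame = pd.DataFrame(index=anova.table.index)
    frame["converged"] = converged
    for g in scheme.groups:
        for t in scheme.post_times:
            frame[f"changed_{scheme.vs_pre_name(g, t)}"] = chg[(g, t)] & converged
    for a, b in scheme.pairs:
        for t in scheme.post_times:
            frame[f"diff_{scheme.pair_name(a, b, t)}"] = btw[(a, b, t)] & converged
    frame["specific_label"] = specific.where(converged, NONE_LABEL)
    frame["general_label"] = general.where(converged, NONE_LABEL)
    for t in scheme.post_times:
        frame[f"timereg_{_tlabel(t)}"] = timereg[_tlabel(t)] & converged
    frame["time_regulated"] = timereg["any"] & converged

    thresholds = {
        "alpha_fdr": alpha,
        "p_interaction_floor": p_interaction_floor,
        "p_vs_pre_raw": p_vs_pre,
    }
    return ClassificationTable(
        frame=frame, scheme=scheme, roles=roles, thresholds=thresholds
    )


@dataclass
class CountReport:
    """Count tables in the layout of the study's summary tables."""

    vs_pre: pd.DataFrame               # groups x post times
    between: dict[str, pd.DataFrame]   # time label -> symmetric group matrix
    specific: pd.Series                # per group
    general: pd.Series                 # independent / dependent
    time_reg: pd.Series                # total + per time
    n_transcripts: int
    n_unclassified: int
    thresholds: dict[str, float]

    def to_text(self) -> str:
        lines = []
        th = ", ".join(f"{k}={v:g}" for k, v in sorted(self.thresholds.items()))
        lines.append(f"Classification counts ({self.n_transcripts} transcripts; {th})")
        lines.append(f"Unclassified (non-converged): {self.n_unclassified}")
        lines.append("")
        lines.append("Changed mRNA versus Pre (per group and time):")
        lines.append(self.vs_pre.to_string())
        for tl, mat in self.between.items():
            lines.append("")
            lines.append(f"Changed mRNA between groups at {tl}:")
            lines.append(mat.to_string(na_rep="-"))
        lines.append("")
        lines.append("Changed mRNA versus Pre specific to only one group:")
        lines.append(self.specific.to_frame("group_specific").T.to_string())
        lines.append("")
        lines.append("Changed mRNA versus Pre in both exercise groups:")
        lines.append(self.general.to_frame("count").T.to_string())
        lines.append("")
        lines.append("Time regulated mRNA (all groups, no interaction):")
        lines.append(self.time_reg.to_frame("count").T.to_string())
        return "\n".join(lines) + "\n"

    def write_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.vs_pre.to_csv(out / "counts_vs_pre.tsv", sep="\t", index_label="group")
        for tl, mat in self.between.items():
            mat.to_csv(out / f"counts_between_{tl}.tsv", sep="\t", index_label="group")
        self.specific.to_csv(out / "counts_specific.tsv", sep="\t", header=["count"])
        self.general.to_csv(out / "counts_general.tsv", sep="\t", header=["count"])
        self.time_reg.to_csv(out / "counts_time_regulated.tsv", sep="\t", header=["count"])
        (out / "counts_report.txt").write_text(self.to_text(), encoding="utf-8")


def build_count_report(classification: ClassificationTable) -> CountReport:
    """Aggregate the per-transcript flags into the six summary count tables."""
    ct = classification
    frame = ct.frame
    scheme = ct.scheme
    groups = list(scheme.groups)
    tlabels = [_tlabel(t) for t in scheme.post_times]

    vs_pre = pd.DataFrame(index=groups, columns=tlabels, dtype=int)
    for g in groups:
        for t, tl in zip(scheme.post_times, tlabels):
            vs_pre.loc[g, tl] = int(frame[f"changed_{scheme.vs_pre_name(g, t)}"].sum())

    between = {}
    for t, tl in zip(scheme.post_times, tlabels):
        mat = pd.DataFrame(np.nan, index=groups, columns=groups)
        for a, b in scheme.pairs:
            n = int(frame[f"diff_{scheme.pair_name(a, b, t)}"].sum())
            mat.loc[a, b] = n
            mat.loc[b, a] = n
        between[tl] = mat

    specific = pd.Series(
        {g: int((frame["specific_label"] == g).sum()) for g in groups}
    )
    general = pd.Series(
        {
            "independent": int((frame["general_label"] == "independent").sum()),
            "dependent": int((frame["general_label"] == "dependent").sum()),
        }
    )
    time_reg = pd.Series(
        {
            "total": int(frame["time_regulated"].sum()),
            **{tl: int(frame[f"timereg_{tl}"].sum()) for tl in tlabels},
        }
    )
    return CountReport(
        vs_pre=vs_pre,
        between=between,
        specific=specific,
        general=general,
        time_reg=time_reg,
        n_transcripts=len(frame),
        n_unclassified=int((~frame["converged"]).sum()),
        thresholds=ct.thresholds,
    )
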