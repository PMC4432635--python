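"""Rule engine: hand-enumerated fixtures and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from exanova import (
    ConfigError,
    GroupRoles,
    build_count_report,
    changed_between_groups,
    changed_vs_pre,
    classify_transcripts,
    exercise_general,
    group_specific,
    infer_roles,
    time_regulated,
)
from exanova.anova import AnovaResult, ContrastScheme, ModelSpec, make_group_codes

GROUPS = ("Control", "Endurance", "Resistance")
TIMES = (2.5, 5.0)
SCHEME = ContrastScheme(GROUPS, TIMES, make_group_codes(GROUPS))


def make_anova_result(rows: dict) -> AnovaResult:
    """Hand-built q/p table; unspecified cells default to insignificance."""
    columns = {}
    names = []
    for t in TIMES:
        names.append(SCHEME.marginal_name(t))
    for g in GROUPS:
        for t in TIMES:
            names.append(SCHEME.vs_pre_name(g, t))
    for a, b in SCHEME.pairs:
        for t in TIMES:
            names.append(SCHEME.pair_name(a, b, t))
    index = list(rows)
    for name in names:
        columns[f"{name}.p"] = [rows[tid].get(f"{name}.p", 0.5) for tid in index]
        columns[f"{name}.q"] = [rows[tid].get(f"{name}.q", 0.5) for tid in index]
    for eff in ("Time", "Group", "TimexGroup", "TimexGroupVsPre"):
        columns[f"{eff}.p"] = [rows[tid].get(f"{eff}.p", 0.5) for tid in index]
        columns[f"{eff}.q"] = [rows[tid].get(f"{eff}.q", 0.5) for tid in index]
    table = pd.DataFrame(columns, index=index)
    table["converged"] = [rows[tid].get("converged", True) for tid in index]
    return AnovaResult(table=table, scheme=SCHEME, spec=ModelSpec())


SIG = 0.01


class TestSingleRules:
    def test_changed_vs_pre_flags_only_the_significant_cell(self):
        res = make_anova_result({"t": {"E2.5h.q": SIG}})
        flags = changed_vs_pre(res)
        assert flags.loc["t", ("Endurance", 2.5)]
        assert flags.loc["t"].sum() == 1

    def test_all_q_one_flags_nothing(self):
        res = make_anova_result({"t": {f"{n}.q": 1.0 for n in ["E2.5h", "S5h"]}})
        assert changed_vs_pre(res).loc["t"].sum() == 0

    def test_changed_between_symmetric_lookup(self):
        res = make_anova_result({"t": {"EvC2.5h.q": SIG}})
        btw = changed_between_groups(res)
        assert btw.loc["t", ("Endurance", "Control", 2.5)]
        assert btw.loc["t"].sum() == 1

    def test_missing_contrast_column_is_configuration_error(self):
        res = make_anova_result({"t": {}})
        res.table = res.table.drop(columns=["E2.5h.q"])
        with pytest.raises(ConfigError, match="E2.5h.q"):
            changed_vs_pre(res)

    def test_interaction_floor_excludes_regardless_of_other_columns(self):
        res = make_anova_result(
            {
                "t": {
                    "TimexGroupVsPre.p": 0.05,
                    "Time2.5h.q": SIG,
                    "C2.5h.p": SIG,
                    "E2.5h.p": SIG,
                    "S2.5h.p": SIG,
                }
            }
        )
        flags = time_regulated(res)
        assert not flags.loc["t", "any"]

    def test_time_regulated_flagged_at_one_time_only(self):
        res = make_anova_result(
            {
                "t": {
                    "TimexGroupVsPre.p": 0.5,
                    "Time2.5h.q": SIG,
                    "C2.5h.p": 0.01,
                    "E2.5h.p": 0.01,
                    "S2.5h.p": 0.01,
                    "Time5h.q": SIG,
                    "C5h.p": 0.2,
                    "E5h.p": 0.01,
                    "S5h.p": 0.01,
                }
            }
        )
        flags = time_regulated(res)
        assert flags.loc["t", "2.5h"]
        assert not flags.loc["t", "5h"]
        assert flags.loc["t", "any"]


def hand_fixture() -> AnovaResult:
    """Five transcripts exercising every clause of the label rules.

    hand-enumerated expectations:
      spec_pos   -> specific Endurance (changed + both pair contrasts at 5h,
                    other groups never changed)
      spec_excl  -> Resistance also changed, so the exclusion clause clears
                    the specific label; both exercise arms changed with a
                    significant between-exercise contrast => dependent
      gen_indep  -> both exercise arms changed, no between-exercise signal
      gen_dep    -> both arms changed, SvE significant; also carries a
                    full per-time vs-Pre pattern but an interaction p below
                    the floor, so it is NOT time-regulated
      timereg    -> all three groups changed at 2.5h with quiet interaction
                    => time-regulated (and exercise-general independent)
    """
    return make_anova_result(
        {
            "spec_pos": {
                "E5h.q": SIG,
                "EvC5h.q": SIG,
                "SvE5h.q": SIG,
            },
            "spec_excl": {
                "E5h.q": SIG,
                "EvC5h.q": SIG,
                "SvE5h.q": SIG,
                "S2.5h.q": SIG,
            },
            "gen_indep": {
                "E5h.q": SIG,
                "S5h.q": SIG,
            },
            "gen_dep": {
                "E2.5h.q": SIG,
                "S2.5h.q": SIG,
                "SvE5h.q": SIG,
                "TimexGroupVsPre.p": 0.02,
                "Time2.5h.q": SIG,
                "C2.5h.p": 0.01,
                "E2.5h.p": 0.01,
                "S2.5h.p": 0.01,
            },
            "timereg": {
                "C2.5h.q": SIG,
                "E2.5h.q": SIG,
                "S2.5h.q": SIG,
                "TimexGroupVsPre.p": 0.6,
                "Time2.5h.q": SIG,
                "C2.5h.p": 0.01,
                "E2.5h.p": 0.01,
                "S2.5h.p": 0.01,
            },
        }
    )


class TestHandEnumeratedFixture:
    def test_labels_match_hand_enumeration(self):
        res = hand_fixture()
        ct = classify_transcripts(res)
        f = ct.frame
        assert f.loc["spec_pos", "specific_label"] == "Endurance"
        assert f.loc["spec_excl", "specific_label"] == "none"
        assert f.loc["gen_indep", "specific_label"] == "none"
        assert f.loc["spec_pos", "general_label"] == "none"
        assert f.loc["spec_excl", "general_label"] == "dependent"
        assert f.loc["gen_indep", "general_label"] == "independent"
        assert f.loc["gen_dep", "general_label"] == "dependent"
        assert not f.loc["gen_dep", "time_regulated"]
        assert f.loc["timereg", "time_regulated"]
        assert f.loc["timereg", "timereg_2.5h"]
        assert not f.loc["timereg", "timereg_5h"]
        assert f.loc["timereg", "specific_label"] == "none"
        assert f.loc["timereg", "general_label"] == "independent"

    def test_counts_match_hand_enumeration(self):
        ct = classify_transcripts(hand_fixture())
        report = build_count_report(ct)
        assert report.specific["Endurance"] == 1
        assert report.specific["Control"] == 0
        assert report.general["independent"] == 2  # gen_indep + timereg
        assert report.general["dependent"] == 2    # spec_excl + gen_dep
        assert report.time_reg["total"] == 1
        assert report.time_reg["2.5h"] == 1
        assert report.time_reg["5h"] == 0
        # vs-Pre table: E5h changed in spec_pos, spec_excl, gen_indep
        assert report.vs_pre.loc["Endurance", "5h"] == 3
        assert report.vs_pre.loc["Control", "2.5h"] == 1  # timereg only

    def test_between_count_matrices_symmetric_with_empty_diagonal(self):
        report = build_count_report(classify_transcripts(hand_fixture()))
        for mat in report.between.values():
            arr = mat.to_numpy(dtype=float)
            assert np.allclose(arr, arr.T, equal_nan=True)
            assert np.isnan(np.diag(arr)).all()

    def test_nonconverged_rows_stay_unlabelled_and_counted(self):
        res = make_anova_result(
            {
                "good": {"E5h.q": SIG, "EvC5h.q": SIG, "SvE5h.q": SIG},
                "bad": {"E5h.q": SIG, "EvC5h.q": SIG, "SvE5h.q": SIG,
                        "converged": False},
            }
        )
        ct = classify_transcripts(res)
        assert ct.frame.loc["good", "specific_label"] == "Endurance"
        assert ct.frame.loc["bad", "specific_label"] == "none"
        report = build_count_report(ct)
        assert report.n_unclassified == 1
        assert report.specific["Endurance"] == 1


class TestInvariants:
    def test_specific_and_general_mutually_exclusive(self, small_dataset):
        from exanova import run_pipeline

        matrix, design, _ = small_dataset
        result = run_pipeline(matrix, design)
        f = result.classification.frame
        both = (f.specific_label != "none") & (f.general_label != "none")
        assert not both.any()

    def test_rule_engine_pure_function_of_table(self):
        res = hand_fixture()
        a = classify_transcripts(res).frame
        b = classify_transcripts(res).frame
        pd.testing.assert_frame_equal(a, b)
        shuffled = AnovaResult(
            table=res.table.iloc[::-1], scheme=res.scheme, spec=res.spec
        )
        c = classify_transcripts(shuffled).frame
        pd.testing.assert_frame_equal(a, c.loc[a.index])

    def test_roles_inference_prefers_control_label(self):
        roles = infer_roles(("Endurance", "control", "Resistance"))
        assert roles.control == "control"
        assert roles.exercise == ("Endurance", "Resistance")
        roles2 = infer_roles(("A", "B"))
        assert roles2.control == "A"

    def test_thresholds_recorded_and_written(self, tmp_path):
        ct = classify_transcripts(hand_fixture(), alpha=0.05)
        assert ct.thresholds["alpha_fdr"] == 0.05
        path = tmp_path / "cls.tsv"
        ct.write(path)
        text = path.read_text()
        assert text.startswith("# alpha_fdr = 0.05")
        back = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        assert len(back) == len(ct.frame)
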