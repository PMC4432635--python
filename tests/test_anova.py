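"""Mixed-model engine: exact limits, oracle agreement, invariances."""

import warnings

import numpy as np
import pandas as pd
import pytest

from exanova import DesignError, ModelSpec, fit_all, fit_transcript
from exanova.preprocess import RatioMatrix
from conftest import make_design, make_ratio_rows
from oracles import classical_rm_anova


def _as_data_dict(row, design, post):
    t = design.table
    return {
        (g, s): np.array(
            [row[t.index[(t.subject_id == s) & (t.time_h == tp)][0]] for tp in post]
        )
        for g in design.groups
        for s in design.subjects_in_group(g)
    }


class TestPerfectSignal:
    def test_pure_endurance_shift_recovered_exactly(self, study_design):
        t = study_design.table
        row = pd.Series(0.0, index=t.index)
        row[t.index[(t.group == "Endurance") & (t.time_h > 0)]] = 1.0
        res = fit_transcript(row.rename("tx"), study_design)
        assert res["E2.5h.est"] == pytest.approx(1.0, abs=1e-12)
        assert res["E5h.est"] == pytest.approx(1.0, abs=1e-12)
        assert res["C2.5h.est"] == pytest.approx(0.0, abs=1e-12)
        # zero noise: the interaction and the endurance contrasts are certain
        assert res["TimexGroupVsPre.p"] == 0.0
        assert res["E5h.p"] == 0.0
        assert res["S5h.p"] == 1.0  # estimate exactly zero with zero variance

    def test_all_zero_transcript_is_degenerate_null(self, study_design):
        row = pd.Series(0.0, index=study_design.table.index)
        res = fit_transcript(row, study_design)
        assert res["E2.5h.est"] == 0.0
        assert res["E2.5h.p"] == 1.0
        assert res["sigma2_resid"] == 0.0


class TestClassicalEquivalence:
    def test_balanced_reml_equals_sums_of_squares_anova(self, study_design):
        rng = np.random.default_rng(31)
        means = {
            (i, g, tp): rng.normal(0, 0.5)
            for i in range(40)
            for g in study_design.groups
            for tp in (2.5, 5.0)
        }
        ratios = make_ratio_rows(study_design, 40, rng, cell_means=means)
        res = fit_all(ratios, study_design)
        interior = res.table.sigma2_subject > 0
        assert interior.mean() > 0.9
        for i in np.flatnonzero(interior.to_numpy()):
            data = _as_data_dict(ratios.iloc[i], study_design, [2.5, 5.0])
            f_t, f_i, f_g, ms_w, ms_b = classical_rm_anova(
                data, study_design.groups, [2.5, 5.0]
            )
            assert res.table["Time.F"].iloc[i] == pytest.approx(f_t, abs=1e-8)
            assert res.table["TimexGroup.F"].iloc[i] == pytest.approx(f_i, abs=1e-8)
            assert res.table["Group.F"].iloc[i] == pytest.approx(f_g, abs=1e-6)
            # variance components match method-of-moments closed forms
            assert res.table["sigma2_resid"].iloc[i] == pytest.approx(ms_w, abs=1e-6)
            assert res.table["sigma2_subject"].iloc[i] == pytest.approx(
                (ms_b - ms_w) / 2.0, abs=1e-6
            )

    def test_agrees_with_statsmodels_mixedlm(self, study_design):
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(77)
        ratios = make_ratio_rows(study_design, 6, rng)
        res = fit_all(ratios, study_design)
        t = study_design.table
        post = t[t.time_h > 0]
        checked = 0
        for i in range(len(ratios)):
            if res.table.sigma2_subject.iloc[i] == 0:
                continue
            y = ratios.iloc[i][post.index].to_numpy()
            dummies = pd.get_dummies(
                pd.Categorical([f"{g}_{tp}" for g, tp in zip(post.group, post.time_h)])
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = MixedLM(
                        y, dummies.to_numpy(float), groups=post.subject_id.to_numpy()
                    ).fit(reml=True, method="lbfgs")
                except np.linalg.LinAlgError:
                    continue
            if not fit.converged:
                continue
            assert float(np.asarray(fit.cov_re)[0, 0]) == pytest.approx(
                res.table.sigma2_subject.iloc[i], abs=1e-4
            )
            assert float(fit.scale) == pytest.approx(
                res.table.sigma2_resid.iloc[i], abs=1e-4
            )
            j = list(dummies.columns).index("Endurance_5.0")
            assert float(fit.params[j]) == pytest.approx(
                res.table["E5h.est"].iloc[i], abs=1e-5
            )
            assert float(fit.bse[j]) == pytest.approx(
                res.table["E5h.se"].iloc[i], abs=1e-4
            )
            checked += 1
        assert checked >= 3


class TestBatchProperties:
    def test_row_order_invariance(self, study_design):
        rng = np.random.default_rng(5)
        ratios = make_ratio_rows(study_design, 30, rng)
        res = fit_all(ratios, study_design)
        perm = rng.permutation(len(ratios))
        res_perm = fit_all(ratios.iloc[perm], study_design)
        realigned = res_perm.table.loc[res.table.index]
        for col in res.table.columns:
            a, b = res.table[col].to_numpy(), realigned[col].to_numpy()
            assert np.array_equal(a, b), col

    def test_single_transcript_matches_batch(self, study_design):
        rng = np.random.default_rng(6)
        ratios = make_ratio_rows(study_design, 4, rng)
        batch = fit_all(ratios, study_design)
        solo = fit_transcript(ratios.iloc[2], study_design)
        pd.testing.assert_series_equal(
            solo, batch.table.iloc[2], check_names=False
        )

    def test_chunking_does_not_change_results(self, study_design):
        rng = np.random.default_rng(8)
        ratios = make_ratio_rows(study_design, 25, rng)
        a = fit_all(ratios, study_design, ModelSpec(chunk_size=7))
        b = fit_all(ratios, study_design, ModelSpec(chunk_size=2048))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_estimate_recovery_of_planted_shift(self, study_design):
        rng = np.random.default_rng(9)
        delta = 1.0
        n = 300
        means = {(i, "Resistance", 5.0): delta for i in range(n)}
        ratios = make_ratio_rows(study_design, n, rng, cell_means=means)
        res = fit_all(ratios, study_design)
        ests = res.table["S5h.est"]
        se = res.table["S5h.se"].mean()
        assert abs(ests.mean() - delta) < 3 * se / np.sqrt(n)


class TestUnbalancedAndErrors:
    def test_missing_post_sample_still_fits(self, study_design):
        dropped = study_design.table.drop(index="Resistance04_5h")
        design = type(study_design)(table=dropped)
        rng = np.random.default_rng(10)
        ratios = make_ratio_rows(design, 10, rng)
        for method in ("containment", "satterthwaite"):
            res = fit_all(ratios, design, ModelSpec(df_method=method))
            pvals = res.table[[c for c in res.table.columns if c.endswith(".p")]]
            arr = pvals.to_numpy()
            assert np.nanmin(arr) >= 0 and np.nanmax(arr) <= 1
            assert res.table.converged.all()

    def test_satterthwaite_df_between_strata_bounds(self, study_design):
        rng = np.random.default_rng(11)
        ratios = make_ratio_rows(study_design, 50, rng, sigma_subject=1.0)
        res = fit_all(ratios, study_design, ModelSpec(df_method="satterthwaite"))
        # contrast p-values must be proper probabilities
        for col in ("E2.5h.p", "SvE5h.p", "Time2.5h.p"):
            assert res.table[col].between(0, 1).all()

    def test_single_subject_group_rejected(self):
        design = make_design(n_subjects=1)
        rng = np.random.default_rng(1)
        ratios = make_ratio_rows(design, 2, rng)
        with pytest.raises(DesignError, match="subject"):
            fit_all(ratios, design)

    def test_invalid_df_method_rejected(self):
        from exanova import ConfigError

        with pytest.raises(ConfigError, match="df_method"):
            ModelSpec(df_method="kenward")
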