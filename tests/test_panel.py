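"""Panel data model, PGSI scoring, and paired descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from symptomnet.panel import (ColumnMap, RiskCategory, SymptomPanel,
                              classify_risk, cronbach_alpha, dichotomize,
                              mcnemar, paired_t, prevalence_table,
                              read_panel, score_pgsi, write_panel)


class TestPanelIO:
    def test_round_trip_identity(self, toy_panel_csv, tmp_path):
        panel = read_panel(toy_panel_csv)
        assert panel.n_persons == 3 and panel.n_items == 9 and panel.n_waves == 2
        assert panel.scale == "ordinal0to3"
        out = tmp_path / "rt.csv"
        write_panel(panel, out)
        again = read_panel(out)
        np.testing.assert_array_equal(panel.responses, again.responses)

    def test_out_of_range_value_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = ["id"] + [f"pg{i}_w{w}" for w in (1, 2) for i in range(1, 10)]
        row = [1] + [4] + [0] * 17
        path.write_text(",".join(header) + "\n" + ",".join(map(str, row)) + "\n")
        with pytest.raises(ValueError, match="above 3"):
            read_panel(path)

    def test_missing_columns_and_duplicate_ids_rejected(self, tmp_path, toy_panel_csv):
        with pytest.raises(ValueError, match="not found"):
            read_panel(toy_panel_csv, ColumnMap(template="x{item}_w{wave}"))
        txt = toy_panel_csv.read_text().splitlines()
        txt.append(txt[1])  # duplicate id 1
        dup = tmp_path / "dup.csv"
        dup.write_text("\n".join(txt) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(dup)

    def test_missing_values_flagged_and_droppable(self, tmp_path):
        path = tmp_path / "miss.csv"
        header = ["id"] + [f"pg{i}_w{w}" for w in (1, 2) for i in range(1, 10)]
        rows = ["1," + ",".join(["0"] * 18),
                "2,," + ",".join(["1"] * 17)]
        path.write_text(",".join(header) + "\n" + "\n".join(rows) + "\n")
        panel = read_panel(path)
        assert panel.complete.tolist() == [True, False]
        assert panel.complete_cases().n_persons == 1
        with pytest.raises(ValueError, match="complete"):
            panel.require_complete()


class TestScoring:
    @pytest.mark.parametrize("responses,total,category", [
        ([0] * 9, 0, RiskCategory.NON_PROBLEMATIC),
        ([1, 1, 1, 0, 0, 0, 0, 0, 0], 3, RiskCategory.MODERATE_RISK),
        ([3] * 9, 27, RiskCategory.SEVERE),
    ])
    def test_pgsi_total_and_category(self, responses, total, category):
        t = score_pgsi(responses)
        assert t == total
        assert classify_risk(t) is category

    @pytest.mark.parametrize("total,category", [
        (0, RiskCategory.NON_PROBLEMATIC), (1, RiskCategory.LOW_RISK),
        (2, RiskCategory.LOW_RISK), (3, RiskCategory.MODERATE_RISK),
        (7, RiskCategory.MODERATE_RISK), (8, RiskCategory.SEVERE),
        (27, RiskCategory.SEVERE),
    ])
    def test_risk_cut_points(self, total, category):
        assert classify_risk(total) is category

    def test_classify_total_and_monotone(self):
        order = [RiskCategory.NON_PROBLEMATIC, RiskCategory.LOW_RISK,
                 RiskCategory.MODERATE_RISK, RiskCategory.SEVERE]
        cats = [order.index(classify_risk(t)) for t in range(28)]
        assert cats == sorted(cats)
        for bad in (-1, 28):
            with pytest.raises(ValueError):
                classify_risk(bad)

    def test_score_rejects_binary_scale(self):
        with pytest.raises(ValueError, match="ordinal"):
            score_pgsi([0, 1] * 4 + [0], scale="binary")


class TestDichotomize:
    def test_mapping_and_idempotence(self):
        resp = np.array([[[0], [1], [2], [3], [0], [1], [2], [3], [0]]])
        panel = SymptomPanel(resp.reshape(1, 9, 1))
        binary = dichotomize(panel)
        assert binary.scale == "binary"
        np.testing.assert_array_equal(
            binary.responses.ravel(), [0, 1, 1, 1, 0, 1, 1, 1, 0])
        again = dichotomize(binary)
        np.testing.assert_array_equal(binary.responses, again.responses)

    def test_all_zero_fixed_point(self):
        panel = SymptomPanel(np.zeros((4, 9, 2), dtype=int))
        assert not dichotomize(panel).responses.any()


class TestPrevalence:
    def test_percentages_from_counts(self):
        # 19 endorsers of symptom 2 among 335
        resp = np.zeros((335, 9, 1), dtype=int)
        resp[:19, 1, 0] = 1
        panel = SymptomPanel(resp, scale="binary")
        tab = prevalence_table(panel)
        row = tab[tab["measure"].str.startswith("2.")].iloc[0]
        assert row["count"] == 19
        assert round(row["percent"], 2) == 5.67

    def test_risk_category_proportions(self):
        # 299 non-problematic, 21 low, 7 moderate, 8 severe (n=335)
        resp = np.zeros((335, 9, 1), dtype=int)
        resp[299:320, 0, 0] = 1                    # total 1 -> low risk
        resp[320:327, 0, 0] = 3                    # total 3 -> moderate
        resp[327:335, :3, 0] = 3                   # total 9 -> severe
        panel = SymptomPanel(resp)
        tab = prevalence_table(panel)
        props = {r["measure"]: round(r["percent"], 2)
                 for _, r in tab.iterrows() if r["measure"].startswith("risk:")}
        assert props["risk:non_problematic"] == 89.25
        assert props["risk:low_risk"] == 6.27
        assert props["risk:severe"] == 2.39

    def test_counts_equal_column_sums(self, rng):
        resp = (rng.random((50, 9, 2)) < 0.3).astype(int)
        panel = SymptomPanel(resp, scale="binary")
        tab = prevalence_table(panel)
        for w, wl in enumerate(panel.wave_labels):
            sums = resp[:, :, w].sum(axis=0)
            got = tab[(tab["wave"] == wl)].set_index("measure")["count"]
            for i, lab in enumerate(panel.item_labels):
                assert got[lab] == sums[i]

    def test_empty_group_rejected(self):
        panel = SymptomPanel(np.zeros((3, 9, 1), dtype=int), scale="binary")
        with pytest.raises(ValueError, match="unknown grouping"):
            prevalence_table(panel, group_by="sex")


class TestCronbach:
    def test_identical_items_give_one(self, rng):
        x = rng.normal(size=(30, 1))
        assert cronbach_alpha(np.hstack([x, x])) == pytest.approx(1.0)

    def test_constructed_covariance_value(self, rng):
        # two items, variances 1, covariance 0.5 -> alpha = 2*(1 - 2/3)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=200_000)
        assert cronbach_alpha(X) == pytest.approx(2 / 3, abs=0.01)

    def test_independent_items_near_zero(self, rng):
        X = rng.normal(size=(10_000, 5))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestPairedT:
    def test_hand_computed_example(self):
        x1 = np.zeros(4)
        x2 = np.array([1.0, 0.0, -1.0, 2.0])
        res = paired_t(x1, x2)
        assert res.extra["mean_diff"] == pytest.approx(0.5)
        assert res.statistic == pytest.approx(0.7746, abs=1e-4)
        assert res.df == 3

    def test_identical_waves(self, rng):
        x = rng.normal(size=20)
        res = paired_t(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy(self, rng):
        x1 = rng.normal(size=40)
        x2 = x1 + rng.normal(0, 0.5, size=40)
        res = paired_t(x1, x2)
        ref = stats.ttest_rel(x2, x1)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_type_i_error_calibrated(self, rng):
        # paired-sample size of the motivating study, null of no change
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x1 = rng.normal(size=335)
            x2 = x1 * 0.3 + rng.normal(size=335)
            if paired_t(x1, x2).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestMcNemar:
    def test_symmetric_discordance(self):
        b1 = np.array([0] * 5 + [1] * 5 + [0] * 10)
        b2 = np.array([1] * 5 + [0] * 5 + [0] * 10)
        res = mcnemar(b1, b2)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_formula_and_exact_binomial(self):
        # b=10 (0->1), c=2 (1->0)
        b1 = np.array([0] * 10 + [1] * 2 + [0] * 8)
        b2 = np.array([1] * 10 + [0] * 2 + [0] * 8)
        res = mcnemar(b1, b2)
        assert res.statistic == pytest.approx(64 / 12)
        assert res.extra["p_binomial"] == pytest.approx(158 / 4096, abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        b1 = np.array([0] * 10 + [1] * 2 + [1] * 5 + [0] * 8)
        b2 = np.array([1] * 10 + [0] * 2 + [1] * 5 + [0] * 8)
        res = mcnemar(b1, b2)
        # paired table: 8 concordant 0s, 10 (0->1), 2 (1->0), 5 concordant 1s
        ref = sm_mcnemar(np.array([[8, 10], [2, 5]]), exact=False, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        ref_exact = sm_mcnemar(np.array([[8, 10], [2, 5]]), exact=True)
        assert res.extra["p_binomial"] == pytest.approx(ref_exact.pvalue)

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_swap_invariance_and_p_range(self, b, c):
        n = b + c + 5
        b1 = np.array([0] * b + [1] * c + [0] * 5)
        b2 = np.array([1] * b + [0] * c + [0] * 5)
        res = mcnemar(b1, b2)
        res_swapped = mcnemar(b2, b1)
        if b + c > 0:
            assert res.statistic == pytest.approx(res_swapped.statistic)
            assert 0 < res.extra["p_binomial"] <= 1
        else:
            assert res.extra["p_binomial"] == 1.0
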