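"""Inferential layer: paired t, repeated-measures ANOVA, Bonferroni."""

import numpy as np
import pandas as pd
import pytest

from gradreveal.stats import bonferroni, null_calibration, paired_t, rm_anova


class TestPairedT:
    def test_identical_samples_give_t0_p1(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_hand_computed_example(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.df == 2
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.mean_diff == pytest.approx(2.0)

    def test_sign_flip_negates_t_preserves_p(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_nonzero_mean_is_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.t)

    def test_matches_scipy(self, rng):
        from scipy import stats as st

        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        res = paired_t(x, y)
        ref = st.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


def _rm_table(data, factors):
    """data: dict subject -> dict cell-tuple -> value."""
    rows = []
    for subj, cells in data.items():
        for cell, value in cells.items():
            row = {"subject": subj, "y": value}
            row.update(dict(zip(factors, cell)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_zero_condition_effect_gives_zero_f(self):
        data = {
            s: {("a",): v, ("b",): v}
            for s, v in zip("stuv", [1.0, 2.0, 3.0, 4.0])
        }
        table = _rm_table(data, ["condition"])
        (eff,) = rm_anova(table, dv="y", within=["condition"])
        assert eff.F == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_sums_of_squares_match_direct_partition(self, rng):
        # 4 subjects x factors A(2) x B(2); oracle computes the classical
        # repeated-measures F from explicit marginal means
        subs = list("wxyz")
        y = rng.standard_normal((4, 2, 2))
        rows = []
        for i, s in enumerate(subs):
            for a in range(2):
                for b in range(2):
                    rows.append({"subject": s, "A": f"a{a}", "B": f"b{b}", "y": y[i, a, b]})
        table = pd.DataFrame(rows)
        effects = {e.name: e for e in rm_anova(table, dv="y", within=["A", "B"])}

        grand = y.mean()
        subj_m = y.mean(axis=(1, 2))
        a_m = y.mean(axis=(0, 2))
        b_m = y.mean(axis=(0, 1))
        n, qa, qb = 4, 2, 2
        ss_a = n * qb * np.sum((a_m - grand) ** 2)
        sa_m = y.mean(axis=2)  # subject x A
        ss_as = qb * np.sum((sa_m - subj_m[:, None] - a_m[None, :] + grand) ** 2)
        F_a = (ss_a / (qa - 1)) / (ss_as / ((n - 1) * (qa - 1)))
        assert effects["A"].F == pytest.approx(F_a, abs=1e-8)
        assert effects["A"].df_num == 1 and effects["A"].df_den == 3

        ss_b = n * qa * np.sum((b_m - grand) ** 2)
        sb_m = y.mean(axis=1)
        ss_bs = qa * np.sum((sb_m - subj_m[:, None] - b_m[None, :] + grand) ** 2)
        F_b = (ss_b / (qb - 1)) / (ss_bs / ((n - 1) * (qb - 1)))
        assert effects["B"].F == pytest.approx(F_b, abs=1e-8)

    def test_subject_relabelling_leaves_f_unchanged(self, rng):
        y = rng.standard_normal((5, 2))
        rows = [
            {"subject": s, "condition": c, "y": y[i, j]}
            for i, s in enumerate("abcde")
            for j, c in enumerate(["lo", "hi"])
        ]
        table = pd.DataFrame(rows)
        (f1,) = rm_anova(table, dv="y", within=["condition"])
        permuted = table.copy()
        permuted["subject"] = permuted["subject"].map(
            dict(zip("abcde", "eabdc"))
        )
        (f2,) = rm_anova(permuted, dv="y", within=["condition"])
        assert f1.F == pytest.approx(f2.F)

    def test_two_level_anova_equals_squared_paired_t(self, rng):
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        rows = [{"subject": i, "condition": "x", "y": v} for i, v in enumerate(x)]
        rows += [{"subject": i, "condition": "y", "y": v} for i, v in enumerate(y)]
        (eff,) = rm_anova(pd.DataFrame(rows), dv="y", within=["condition"])
        t = paired_t(x, y)
        assert eff.F == pytest.approx(t.t**2, abs=1e-8)
        assert eff.p == pytest.approx(t.p, abs=1e-10)

    def test_scale_equivariance(self, rng):
        y = rng.standard_normal((6, 2)) + 3
        rows = [
            {"subject": i, "condition": c, "y": y[i, j]}
            for i in range(6)
            for j, c in enumerate(["lo", "hi"])
        ]
        table = pd.DataFrame(rows)
        (f1,) = rm_anova(table, dv="y", within=["condition"])
        table2 = table.assign(y=table["y"] * 7.3)
        (f2,) = rm_anova(table2, dv="y", within=["condition"])
        assert f1.F == pytest.approx(f2.F)
        assert f1.p == pytest.approx(f2.p)

    def test_single_level_factor_rejected(self):
        table = pd.DataFrame(
            {"subject": [1, 2, 3], "condition": ["a"] * 3, "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="levels"):
            rm_anova(table, dv="y", within=["condition"])

    def test_incomplete_subjects_dropped_with_warning(self, rng, caplog):
        rows = [
            {"subject": s, "condition": c, "y": rng.standard_normal()}
            for s in "abcd"
            for c in ("lo", "hi")
        ]
        rows = rows[:-1]  # subject 'd' misses one cell
        with caplog.at_level("WARNING", logger="gradreveal.stats"):
            (eff,) = rm_anova(pd.DataFrame(rows), dv="y", within=["condition"])
        assert "missing cells" in caplog.text
        assert eff.df_den == 2  # 3 complete subjects remain


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 6)[0] == 1.0

    def test_monotone_and_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=8))
        adj = bonferroni(p, 8)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)


class TestNullCalibration:
    def test_alpha_zero_never_rejects(self):
        cfg = {"n_subjects": 4, "n_trials": 12}
        rate = null_calibration(cfg, n_reps=3, alpha=0.0, seed=0)
        assert rate == 0.0

    def test_large_effect_is_detected(self):
        from gradreveal.synth import GroundTruth

        gt = GroundTruth(
            drift_rate={"neutral": 0.10, "high": 0.07},
            threshold={"neutral": 1.0, "high": 1.0},
            rt_noise_sd=1.5,
        )
        cfg = {"n_subjects": 10, "n_trials": 30, "ground_truth": gt}
        rate = null_calibration(cfg, n_reps=10, alpha=0.05, seed=1)
        assert rate >= 0.8
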