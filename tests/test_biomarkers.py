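"""Integration patterns, group tests, partial correlations, clinical rules."""

import numpy as np
import pytest

from icnmhe import (
    ClinicalCoupling,
    ClinicalCutoffs,
    SimulationConfig,
    bonferroni_flags,
    chi_square_2x2,
    demographics_table,
    diagnose_mhe,
    group_difference_tests,
    partial_correlation,
    roi_meanfc_metric,
    roi_size_metric,
    simulate_clinical,
    ttest_from_summary,
)
from icnmhe.cohort import SubjectRecord


def _record(**kw):
    base = dict(
        subject_id="S001", group="NMHE", tmt_a=40.0, tmt_b=120.0, dst=35.0,
        bdt=25.0, child_pugh=6.0, age=50.0, gender="M", education=9.0,
        movement=0.1,
    )
    base.update(kw)
    return SubjectRecord(**base)


class TestRoiMetrics:
    def test_size_counts_overlap(self):
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[1:4, 1:4, 1:4] = True  # 27 voxels
        assert roi_size_metric(np.ones((4, 4, 4), dtype=bool), roi) == 27
        assert roi_size_metric(np.zeros((4, 4, 4), dtype=bool), roi) == 0
        half = np.zeros((4, 4, 4), dtype=bool)
        half[1:4, 1:4, 1:2] = True  # 9 of the 27
        assert roi_size_metric(half, roi) == 9

    def test_mean_fc_is_roi_mean_only(self):
        roi = np.zeros((2, 2, 3), dtype=bool)
        roi[0, 0, :] = True
        fmap = np.zeros((2, 2, 3))
        fmap[0, 0, :] = [1.0, 2.0, 3.0]
        fmap[1, 1, 1] = 99.0  # outside the ROI, must not matter
        assert roi_meanfc_metric(fmap, roi) == pytest.approx(2.0)
        assert roi_meanfc_metric(np.full((2, 2, 3), 7.0), roi) == pytest.approx(7.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_size_metric(np.ones((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool))

    def test_overlap_monotone_in_threshold(self, planted_zmaps):
        """D shrinks as the threshold grows, so the ROI overlap count cannot rise."""
        zmaps, labels, mask, planted = planted_zmaps
        from icnmhe.gamma import roi_volume

        roi = roi_volume(planted.voxels, mask.shape)
        for z in zmaps[sorted(zmaps)[planted.icn]]:
            counts = [roi_size_metric(z > t, roi) for t in np.arange(1.0, 3.01, 0.25)]
            assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestGroupDifference:
    def test_identical_groups_t_zero_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["MHE"] * 3 + ["NMHE"] * 3)
        res = group_difference_tests(v, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_pooled_t_oracle(self):
        a = np.array([3.1, 2.9, 3.4, 3.7])
        b = np.array([2.0, 2.2, 1.8])
        # closed-form pooled-variance t computed independently
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        v = np.concatenate([a, b])
        g = np.array(["MHE"] * 4 + ["NMHE"] * 3)
        res = group_difference_tests(v, g)
        assert res.statistic == pytest.approx(t_oracle, abs=1e-9)

    def test_degenerate_zero_variance_flagged(self):
        v = np.array([2.0, 2.0, 2.0, 2.0])
        g = np.array(["MHE", "MHE", "NMHE", "NMHE"])
        assert group_difference_tests(v, g).degenerate


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        res = partial_correlation(x, y)
        assert res.statistic == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_y_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        c = rng.normal(size=25)
        res = partial_correlation(x, c, c[:, None])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(2)
        n, k = 40, 3
        c = rng.normal(size=(n, k))
        x = c @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        y = c @ [-0.3, 0.4, 0.2] + 0.6 * x + rng.normal(size=n)
        res = partial_correlation(x, y, c)
        # oracle: negated scaled off-diagonal of the precision matrix
        m = np.column_stack([x, y, c])
        prec = np.linalg.inv(np.corrcoef(m.T))
        r_oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert res.statistic == pytest.approx(r_oracle, abs=1e-9)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(35, 4)), columns=["x", "y", "c1", "c2"])
        ours = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert ours.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        c = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, c)

    def test_child_pugh_sign_recovered_in_coupled_replicates(self):
        """With Child-Pugh negatively coupled to planted connectivity, the
        partial correlation (controlling movement/age/gender/education) is
        negative in nearly all replicate cohorts."""
        from icnmhe.cohort import planted_integrations

        negative = 0
        reps = 20
        for rep in range(reps):
            cfg = SimulationConfig(
                n_mhe=32, n_nmhe=42, grid_shape=(14, 16, 14), n_templates=2,
                n_timepoints=20, seed=500 + rep,
            )
            integ = planted_integrations(cfg)
            recs = [
                simulate_clinical(
                    "MHE" if gi < 1 else "NMHE", gi, ClinicalCoupling(), seed=rep * 100 + i
                )
                for i, gi in enumerate(integ)
            ]
            cp = np.array([r.child_pugh for r in recs])
            cov = np.column_stack(
                [
                    [r.movement for r in recs],
                    [r.age for r in recs],
                    [1.0 if r.gender == "M" else 0.0 for r in recs],
                    [r.education for r in recs],
                ]
            )
            res = partial_correlation(integ, cp, cov)
            negative += res.statistic < 0
        assert negative >= 0.9 * reps


class TestBonferroni:
    def test_family_of_three_bound(self):
        flags = bonferroni_flags([0.015, 0.027, 0.02], family_size=3)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_family_of_one_is_plain_alpha(self):
        assert bonferroni_flags([0.04], 1)[0]


class TestDiagnosis:
    def test_two_impairments_is_mhe(self):
        rec = _record(tmt_a=70.0, dst=20.0)
        assert diagnose_mhe(rec) == "MHE"

    def test_single_impairment_is_nmhe(self):
        rec = _record(tmt_b=160.0)
        assert diagnose_mhe(rec) == "NMHE"

    def test_all_four_impaired_is_mhe(self):
        rec = _record(tmt_a=80.0, tmt_b=200.0, dst=10.0, bdt=10.0)
        assert diagnose_mhe(rec) == "MHE"

    def test_cutoffs_are_strict_boundaries(self):
        # exactly at the cutoffs: not impaired on any test
        rec = _record(tmt_a=68.0, tmt_b=156.0, dst=23.0, bdt=16.0)
        assert diagnose_mhe(rec, ClinicalCutoffs()) == "NMHE"


class TestChiSquare:
    def test_overt_he_history_table(self):
        res = chi_square_2x2([[10, 32], [11, 21]])
        assert res.p == pytest.approx(0.32, abs=0.005)

    def test_symmetric_table_is_null(self):
        res = chi_square_2x2([[7, 13], [7, 13]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_expected_counts_oracle(self):
        table = np.array([[12.0, 8.0], [5.0, 15.0]])
        rows, cols, n = table.sum(1), table.sum(0), table.sum()
        expected = np.outer(rows, cols) / n
        chi2_oracle = ((table - expected) ** 2 / expected).sum()
        assert chi_square_2x2(table).statistic == pytest.approx(chi2_oracle, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [3, 4]])


class TestTTestFromSummary:
    def test_tmt_a_group_difference_is_extreme(self):
        res = ttest_from_summary(47.3, 16.9, 42, 75.2, 19.8, 32)
        assert res.p < 0.001

    def test_equal_means_null(self):
        res = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_raw_data_with_same_summaries(self):
        # construct samples with exactly the requested mean and SD
        def sample(m, s, n, seed):
            v = np.random.default_rng(seed).normal(size=n)
            v = (v - v.mean()) / v.std(ddof=1)
            return m + s * v

        a = sample(10.0, 2.0, 20, 0)
        b = sample(8.5, 2.5, 25, 1)
        from scipy import stats

        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        res = ttest_from_summary(10.0, 2.0, 20, 8.5, 2.5, 25)
        assert res.statistic == pytest.approx(t_raw, abs=1e-6)
        assert res.p == pytest.approx(p_raw, abs=1e-6)


class TestDemographics:
    def test_table_rows_and_group_summaries(self):
        recs = [
            simulate_clinical("NMHE", 1.0, ClinicalCoupling(), seed=i, subject_id=f"S{i}")
            for i in range(20)
        ] + [
            simulate_clinical("MHE", 0.0, ClinicalCoupling(), seed=100 + i, subject_id=f"T{i}")
            for i in range(15)
        ]
        table = demographics_table(recs)
        assert "TMT-A (seconds)" in table["characteristic"].tolist()
        tmt = table[table["characteristic"] == "TMT-A (seconds)"].iloc[0]
        assert tmt["p"] < 0.01  # planted group gap must be detected
        age = table[table["characteristic"] == "Age (years)"].iloc[0]
        assert age["p"] > 0.001  # no planted age effect
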