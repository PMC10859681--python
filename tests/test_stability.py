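"""ICC estimators, reproducibility bins, rank-sum test, stability report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from radstab import (
    GROUPS,
    anova_mean_squares,
    categorize_icc,
    icc_agreement,
    icc_consistency,
    stability_report,
    wilcoxon_rank_sum,
)

from _oracles import anova_oracle, icc_oracle, random_measurement_table


class TestAnovaMeanSquares:
    def test_all_equal_cells_give_zero(self):
        ms = anova_mean_squares(np.full((4, 3), 2.5))
        assert ms.ms_rows == ms.ms_cols == ms.ms_error == ms.ms_within == 0.0

    def test_two_by_two_hand_computation(self):
        ms = anova_mean_squares([[0, 0], [1, 1]])
        assert ms.ms_rows == 1.0
        assert ms.ms_cols == 0.0
        assert ms.ms_error == 0.0
        assert ms.ms_within == 0.0

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(50):
            t = random_measurement_table(rng, n=10, k=3)
            ms = anova_mean_squares(t)
            oracle = anova_oracle(t)
            assert ms.ms_rows == pytest.approx(oracle["ms_rows"], abs=1e-10)
            assert ms.ms_cols == pytest.approx(oracle["ms_cols"], abs=1e-10)
            assert ms.ms_error == pytest.approx(oracle["ms_error"], abs=1e-10)
            assert ms.ms_within == pytest.approx(oracle["ms_within"], abs=1e-10)

    def test_sum_of_squares_identity(self, rng):
        t = random_measurement_table(rng)
        n, k = t.shape
        ms = anova_mean_squares(t)
        total = ((t - t.mean()) ** 2).sum()
        parts = (ms.ms_rows * (n - 1) + ms.ms_cols * (k - 1)
                 + ms.ms_error * (n - 1) * (k - 1))
        assert parts == pytest.approx(total, rel=1e-9)

    def test_incomplete_table_rejected(self):
        t = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            anova_mean_squares(t)
        with pytest.raises(ValueError):
            anova_mean_squares(np.zeros((1, 3)))


class TestIcc:
    def test_identical_columns_give_exactly_one(self, rng):
        col = rng.normal(size=6)[:, None]
        t = np.repeat(col, 3, axis=1)
        assert icc_agreement(t).value == 1.0
        assert icc_consistency(t).value == 1.0

    def test_column_offset_penalized_only_by_agreement(self, rng):
        col = rng.normal(size=8)
        t = np.column_stack([col, col + 0.7])
        assert icc_consistency(t).value == pytest.approx(1.0, abs=1e-12)
        assert icc_agreement(t).value < 1.0

    def test_matches_variance_component_oracle(self, rng):
        for _ in range(200):
            t = random_measurement_table(rng, n=6, k=2)
            a1, c1 = icc_oracle(t)
            assert icc_agreement(t).value == pytest.approx(a1, abs=1e-10)
            assert icc_consistency(t).value == pytest.approx(c1, abs=1e-10)

    def test_consistency_dominates_agreement_when_raters_vary(self, rng):
        # ICC(C,1) >= ICC(A,1) when the rater mean square is at least the
        # interaction mean square AND the ICC is non-negative: the agreement
        # denominator then carries the extra non-negative (k/n)(MS_C - MS_E)
        # term against a non-negative numerator.  Outside that regime the
        # ordering genuinely reverses.
        seen_reversal = False
        for _ in range(1000):
            t = random_measurement_table(rng)
            ms = anova_mean_squares(t)
            c1 = icc_consistency(t).value
            a1 = icc_agreement(t).value
            if ms.ms_cols >= ms.ms_error and ms.ms_rows >= ms.ms_error:
                assert c1 >= a1 - 1e-12
            elif c1 < a1:
                seen_reversal = True
        assert seen_reversal

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t = random_measurement_table(rng, n=12, k=3)
        n, k = t.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": t.ravel(),
        })
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc_agreement(t).value == pytest.approx(
            res.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc_consistency(t).value == pytest.approx(
            res.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_affine_transform_invariance(self, rng):
        t = random_measurement_table(rng, n=8, k=3)
        for icc in (icc_agreement, icc_consistency):
            base = icc(t).value
            assert icc(3.2 * t - 1.7).value == pytest.approx(base, abs=1e-9)

    def test_subject_relabeling_invariance(self, rng):
        t = random_measurement_table(rng, n=9, k=2)
        perm = rng.permutation(9)
        for icc in (icc_agreement, icc_consistency):
            assert icc(t[perm]).value == pytest.approx(icc(t).value, abs=1e-12)

    def test_single_column_shift_affects_only_agreement(self, rng):
        t = random_measurement_table(rng, n=10, k=3)
        shifted = t.copy()
        shifted[:, 1] += 2.0
        assert icc_consistency(shifted).value == pytest.approx(
            icc_consistency(t).value, abs=1e-9)
        assert icc_agreement(shifted).value < icc_agreement(t).value

    def test_constant_table_is_degenerate_one(self):
        res = icc_agreement(np.full((5, 2), 3.3))
        assert res.value == 1.0 and res.degenerate
        assert res.group == "Excellent"

    def test_zero_consistency_denominator_raises(self):
        # identical rows, distinct columns: MS_R = MS_E = 0
        with pytest.raises(ZeroDivisionError):
            icc_consistency(np.array([[0.0, 1.0], [0.0, 1.0]]))

    def test_printed_formula_variants_differ(self, rng):
        col = rng.normal(size=8)[:, None]
        t = np.repeat(col, 2, axis=1)
        # the published consistency denominator reads MS_R + (k-1) MS_R,
        # which yields 1/k instead of 1 on identical columns
        res = icc_consistency(t, printed_formula=True)
        assert res.value == pytest.approx(0.5, abs=1e-12)
        t2 = random_measurement_table(rng, n=10, k=3)
        assert icc_agreement(t2, printed_formula=True).value != pytest.approx(
            icc_agreement(t2).value)


class TestCategorizeIcc:
    @pytest.mark.parametrize(
        "value,group",
        [
            (0.990, "Excellent"),
            (0.183, "Poor"),
            (0.554, "Fair"),
            (0.39999, "Poor"),
            (0.4, "Fair"),
            (0.6, "Good"),
            (0.75, "Excellent"),
            (1.0, "Excellent"),
            (-0.2, "Poor"),
        ],
    )
    def test_binning(self, value, group):
        assert categorize_icc(value) == group

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            categorize_icc(1.01)

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=200, derandomize=True)
    def test_every_value_lands_in_exactly_one_group(self, value):
        assert categorize_icc(value) in GROUPS


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_rank_sum(x, x)
        assert p == 1.0

    def test_complete_separation_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert w == 10.0
        assert p == pytest.approx(2 / 70)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=6)
        _, p_xy = wilcoxon_rank_sum(x, y)
        _, p_yx = wilcoxon_rank_sum(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_exact_branch_matches_scipy_enumeration(self, rng):
        from scipy import stats as sps

        for _ in range(20):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_large_samples_use_corrected_normal_approximation(self, rng):
        from scipy import stats as sps

        x = rng.normal(size=20)
        y = rng.normal(0.5, 1.0, size=25)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True).pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestStabilityReport:
    def _tables(self, rng, noise, features=6, n=12, k=2):
        out = {}
        for i in range(features):
            subj = rng.normal(0, 2.0, size=(n, 1))
            out[f"feat_{i}"] = subj + rng.normal(0, noise, size=(n, k))
        return out

    def test_identical_sessions_give_all_excellent(self, rng):
        subj = rng.normal(size=(10, 1))
        tables = {"manual": {f"f{i}": np.repeat(subj, 2, axis=1)
                             for i in range(5)}}
        report = stability_report(tables)
        assert (report.per_feature["manual"] == 1.0).all()
        assert report.group_counts.loc["Excellent", "manual"] == 5
        assert report.group_percent.loc["Excellent", "manual"] == 100.0

    def test_group_counts_partition_registry(self, rng):
        tables = {
            "a": self._tables(rng, noise=0.5),
            "b": self._tables(rng, noise=2.0),
        }
        report = stability_report(tables)
        assert (report.group_counts.sum(axis=0) == 6).all()

    def test_noisier_arm_has_lower_mean_icc(self, rng):
        tables = {
            "clean": self._tables(rng, noise=0.2, features=10),
            "noisy": self._tables(rng, noise=3.0, features=10),
        }
        report = stability_report(tables)
        assert report.summary.loc["clean", "mean"] > \
            report.summary.loc["noisy", "mean"]
        p = report.pairwise_wilcoxon.loc["clean", "noisy"]
        assert 0.0 < p <= 1.0

    def test_registry_mismatch_rejected(self, rng):
        tables = {
            "a": self._tables(rng, noise=0.5, features=4),
            "b": self._tables(rng, noise=0.5, features=3),
        }
        with pytest.raises(ValueError, match="registry"):
            stability_report(tables)

    def test_population_sd_in_summary(self, rng):
        tables = {"a": self._tables(rng, noise=0.5, features=8)}
        report = stability_report(tables)
        vals = report.per_feature["a"].to_numpy(dtype=float)
        assert report.summary.loc["a", "sd"] == pytest.approx(
            vals.std(ddof=0), abs=1e-12)
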