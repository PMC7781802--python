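"""Agreement panel statistics: bias, error metrics, ICC(A,2), box plots."""

import numpy as np
import pandas as pd
import pytest

import poseagree as pg
from poseagree.agreement import _anova_two_way
from poseagree.errors import UndefinedStatisticError
from poseagree.pipeline import round_half_up

from conftest import make_pairs


def icc_a2_oracle(x):
    """From-scratch ICC(A,k) by explicit elementwise sums of squares.

    Deliberately loop-based and independent of the vectorised
    implementation under test.
    """
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestBiasStats:
    def test_zero_differences(self):
        p = make_pairs(np.full(100, 90.0), np.full(100, 90.0))
        assert pg.bias_stats(p) == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_reproduces_printed_right_shoulder_ci(self):
        """bias 2.71, SD 10.28, n = 30000 gives the printed CI 2.59 to 2.83."""
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, 30000)
        d = (d - d.mean()) / d.std(ddof=1) * 10.28 + 2.71  # exact moments
        p = make_pairs(d + 90.0, np.full(30000, 90.0))
        bias, sd, se, lo, hi = pg.bias_stats(p)
        assert round_half_up(bias, 2) == 2.71
        assert round_half_up(sd, 2) == 10.28
        assert round_half_up(lo, 2) == 2.59
        assert round_half_up(hi, 2) == 2.83

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        c, r = rng.uniform(0, 180, (2, 50))
        p = make_pairs(c, r)
        bias, sd, se, lo, hi = pg.bias_stats(p)
        d = [c[i] - r[i] for i in range(50)]
        mean = sum(d) / 50
        var = sum((x - mean) ** 2 for x in d) / 49
        assert bias == pytest.approx(mean, abs=1e-12)
        assert sd == pytest.approx(var**0.5, abs=1e-12)
        assert se == pytest.approx(var**0.5 / 50**0.5, abs=1e-12)


class TestErrorMetrics:
    def test_identical_series_all_zero(self):
        p = make_pairs([90.0, 100.0, 110.0], [90.0, 100.0, 110.0])
        assert pg.error_metrics(p) == (0.0, 0.0, 0.0, 0.0)

    def test_smape_bounded_at_200(self):
        """When one method reads 0 and the other does not, the summand hits
        the metric's upper bound of 200%."""
        p = make_pairs([10.0, 10.0], [0.0, 0.0])
        mae, mad, rmse, smape = pg.error_metrics(p)
        assert smape == pytest.approx(200.0)

    def test_smape_zero_over_zero_defined_as_zero(self):
        p = make_pairs([0.0, 10.0], [0.0, 10.0])
        assert pg.error_metrics(p)[3] == 0.0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(2)
        c, r = rng.uniform(1, 180, (2, 50))
        p = make_pairs(c, r)
        mae, mad, rmse, smape = pg.error_metrics(p)
        d = [c[i] - r[i] for i in range(50)]
        assert mae == pytest.approx(sum(abs(x) for x in d) / 50, abs=1e-12)
        med = float(np.median(d))
        assert mad == pytest.approx(
            float(np.median([abs(x - med) for x in d])), abs=1e-12
        )
        assert rmse == pytest.approx((sum(x**2 for x in d) / 50) ** 0.5, abs=1e-12)
        s = sum(
            abs(c[i] - r[i]) / ((abs(c[i]) + abs(r[i])) / 2) for i in range(50)
        )
        assert smape == pytest.approx(100 * s / 50, abs=1e-10)

    def test_mean_deviation_variant_available(self):
        rng = np.random.default_rng(3)
        c, r = rng.uniform(1, 180, (2, 40))
        p = make_pairs(c, r)
        _, mad, _, _ = pg.error_metrics(p, mad_kind="mean")
        d = c - r
        assert mad == pytest.approx(np.abs(d - d.mean()).mean(), abs=1e-12)


class TestRmseFromMoments:
    @pytest.mark.parametrize(
        "bias, sd, n, printed",
        [
            (0.15, 2.03, 30000, 2.04),  # pelvis row
            (-1.01, 12.12, 30000, 12.16),  # right elbow row
        ],
    )
    def test_reproduces_printed_rmse(self, bias, sd, n, printed):
        assert round_half_up(pg.rmse_from_moments(bias, sd, n), 2) == printed

    def test_zero_bias_large_n_limit_is_sd(self):
        assert pg.rmse_from_moments(0.0, 7.5, 10**9) == pytest.approx(
            7.5, rel=1e-8
        )

    def test_exact_identity_with_computed_differences(self):
        rng = np.random.default_rng(4)
        c, r = rng.uniform(0, 180, (2, 200))
        p = make_pairs(c, r)
        bias, sd, *_ = pg.bias_stats(p)
        _, _, rmse, _ = pg.error_metrics(p)
        assert pg.rmse_from_moments(bias, sd, p.n) == pytest.approx(
            rmse, abs=1e-9
        )


class TestIccA2:
    def test_perfect_agreement_is_exactly_one(self):
        x = np.linspace(10, 170, 50)
        p = make_pairs(x, x)
        icc, lo, hi = pg.icc_a2(p)
        assert (icc, lo, hi) == (1.0, 1.0, 1.0)

    def test_toy_matrix_matches_sums_of_squares_oracle(self):
        x = np.array(
            [[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0], [7.0, 6.0], [8.0, 5.0]]
        )
        icc, _, _ = pg.icc_a2(x)
        assert icc == pytest.approx(icc_a2_oracle(x), abs=1e-10)

    def test_fifty_random_matrices_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 31))
            x = rng.normal(0, 5, (n, 2)) + rng.normal(0, 3, (n, 1))
            icc, _, _ = pg.icc_a2(x)
            assert icc == pytest.approx(icc_a2_oracle(x), abs=1e-10)

    def test_matches_pingouin_point_estimate_and_ci(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            x = rng.normal(0, 5, (n, 2)) + rng.normal(0, 3, (n, 1))
            icc, lo, hi = pg.icc_a2(x)
            df = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": np.tile([0, 1], n),
                    "y": x.reshape(-1),
                }
            )
            res = pingouin.intraclass_corr(
                df, targets="targets", raters="raters", ratings="y"
            )
            row = res[res["Type"] == "ICC(A,k)"].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-10)
            assert lo <= icc <= hi + 1e-12
            p_lo, p_hi = row["CI95"]
            if p_lo <= row["ICC"] <= p_hi and -1 <= p_lo and p_hi <= 1:
                # compare where the F-interval is well behaved (at tiny n
                # its denominators can flip sign, and pingouin then reports
                # an inverted interval we deliberately replace); pingouin
                # rounds its CI to 2 decimals
                assert lo == pytest.approx(p_lo, abs=5.1e-3)
                assert hi == pytest.approx(p_hi, abs=5.1e-3)

    def test_zero_between_subject_variance_raises(self):
        x = np.full((10, 2), 42.0)
        with pytest.raises(UndefinedStatisticError):
            pg.icc_a2(x)

    def test_constant_offset_shifts_bias_not_sd_and_lowers_icc(self):
        """Absolute agreement penalises a systematic offset."""
        rng = np.random.default_rng(7)
        ref = 90 + 25 * np.sin(np.linspace(0, 20, 500)) + rng.normal(0, 1, 500)
        cand = ref + rng.normal(0, 2, 500)
        p0 = make_pairs(cand, ref)
        p1 = make_pairs(cand + 5.0, ref)
        b0, sd0, *_ = pg.bias_stats(p0)
        b1, sd1, *_ = pg.bias_stats(p1)
        assert b1 - b0 == pytest.approx(5.0, abs=1e-9)
        assert sd1 == pytest.approx(sd0, abs=1e-9)
        assert pg.icc_a2(p1)[0] < pg.icc_a2(p0)[0]

    def test_icc_decreases_monotonically_with_noise(self):
        """Mean ICC over 200 replicates falls as candidate noise grows."""
        rng = np.random.default_rng(8)
        means = []
        for sd in (0.5, 2.0, 5.0, 10.0):
            vals = []
            for _ in range(50):
                ref = rng.normal(90, 20, 300)
                cand = ref + rng.normal(0, sd, 300)
                vals.append(pg.icc_a2(make_pairs(cand, ref))[0])
            means.append(np.mean(vals))
        assert means[0] > 0.95
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_small_noise_classified_excellent(self):
        rng = np.random.default_rng(9)
        ref = rng.normal(90, 20, 1000)
        cand = ref + rng.normal(0, 2, 1000)
        icc, _, _ = pg.icc_a2(make_pairs(cand, ref))
        assert icc > 0.95
        assert pg.classify_icc(icc) == "excellent"


@pytest.mark.parametrize(
    "icc, expected",
    [
        (0.951, "excellent"),
        (0.75, "excellent"),
        (0.749, "fair-to-good"),
        (0.5, "fair-to-good"),
        (0.40, "fair-to-good"),
        (0.39, "poor"),
        (-0.2, "poor"),
    ],
)
def test_fleiss_classification_bands(icc, expected):
    assert pg.classify_icc(icc) == expected


class TestPerVideoIcc:
    def test_identical_pair_videos_all_one(self):
        x = np.linspace(30, 150, 60)
        groups = [
            make_pairs(x, x, video_id=f"v{i}", joint_name="neck")
            for i in range(10)
        ]
        rows = pg.per_video_icc(groups)
        assert [r["icc"] for r in rows] == [1.0] * 10
        assert not any(r["flagged"] for r in rows)

    def test_one_noisy_video_among_nine_clean_is_flagged(self):
        rng = np.random.default_rng(10)
        x = 90 + 5 * np.sin(np.linspace(0, 20, 200))
        groups = []
        for i in range(9):
            groups.append(
                make_pairs(x + rng.normal(0, 0.2, 200), x, video_id=f"v{i}")
            )
        groups.append(
            make_pairs(x + rng.normal(0, 30, 200), x, video_id="v9")
        )
        rows = pg.per_video_icc(groups)
        flagged = [r["video_id"] for r in rows if r["flagged"]]
        assert flagged == ["v9"]


class TestBoxplotStats:
    def test_uniform_1_to_100(self):
        b = pg.boxplot_stats(np.arange(1.0, 101.0))
        assert b.median == 50.5
        assert b.outliers.size == 0
        assert b.whisker_low == 1.0 and b.whisker_high == 100.0

    def test_single_extreme_outlier(self):
        d = np.concatenate([np.arange(1.0, 101.0), [1000.0]])
        b = pg.boxplot_stats(d)
        np.testing.assert_array_equal(b.outliers, [1000.0])
        assert b.whisker_high <= b.q3 + 1.5 * b.iqr

    def test_quartiles_match_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0, 5, 137)
        b = pg.boxplot_stats(d)
        s = np.sort(d)

        def quantile(q):
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert b.q1 == pytest.approx(quantile(0.25), abs=1e-12)
        assert b.median == pytest.approx(quantile(0.5), abs=1e-12)
        assert b.q3 == pytest.approx(quantile(0.75), abs=1e-12)
        assert all(o < b.whisker_low or o > b.whisker_high for o in b.outliers)


def test_report_internal_consistency(small_study_bundle):
    """Every computed panel row satisfies the moment identity and Jensen."""
    for r in small_study_bundle.reports:
        assert r.rmse**2 == pytest.approx(
            r.bias**2 + r.sd**2 * (r.n - 1) / r.n, abs=1e-9
        )
        assert r.mae <= r.rmse + 1e-12
        assert r.rmse >= abs(r.bias)
        assert 0 <= r.smape <= 200
        assert -1 <= r.icc <= 1
        assert r.ci_low <= r.bias <= r.ci_high
        assert r.icc_ci_low <= r.icc <= r.icc_ci_high + 1e-12
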