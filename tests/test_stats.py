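"""Statistical battery vs independent brute-force implementations, plus the
hand-computed worked examples and the report-table structure."""

import math

import numpy as np
import pandas as pd
import pytest

from suvlean.stats import (
    bland_altman,
    bmi_categorize,
    bmi_subgroup_table,
    build_suv_bmi_table,
    coefficient_of_variation,
    ks_normal,
    lbm_agreement_table,
    linear_regression,
    one_way_anova,
    paired_t,
    pearson_corr,
    unpaired_t,
)

# ---- brute-force oracles (pure python, independent of numpy/scipy paths) ----


def bf_mean(x):
    return sum(x) / len(x)


def bf_sd(x):
    m = bf_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def bf_pearson(x, y):
    mx, my = bf_mean(x), bf_mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def bf_ols(x, y):
    mx, my = bf_mean(x), bf_mean(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    return slope, my - slope * mx


def bf_paired_t(a, b):
    d = [u - v for u, v in zip(a, b)]
    return bf_mean(d) / (bf_sd(d) / math.sqrt(len(d)))


def bf_unpaired_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * bf_sd(a) ** 2 + (nb - 1) * bf_sd(b) ** 2) / (na + nb - 2)
    return (bf_mean(a) - bf_mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))


def bf_anova_f(groups):
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = bf_mean([v for g in groups for v in g])
    ssb = sum(len(g) * (bf_mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - bf_mean(g)) ** 2 for v in g) for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


def _random_case(rng, n):
    return list(rng.normal(size=n) * rng.uniform(0.5, 5) + rng.uniform(-3, 3))


@pytest.mark.parametrize("seed", range(10))
def test_statistics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 20))
    x, y = _random_case(rng, n), _random_case(rng, n)

    r, _ = pearson_corr(x, y)
    assert r == pytest.approx(bf_pearson(x, y), abs=1e-10)

    reg = linear_regression(x, y)
    slope, intercept = bf_ols(x, y)
    assert reg.slope == pytest.approx(slope, abs=1e-10)
    assert reg.intercept == pytest.approx(intercept, abs=1e-10)
    assert reg.r_squared == pytest.approx(reg.r**2, abs=1e-12)

    assert paired_t(x, y)[0] == pytest.approx(bf_paired_t(x, y), abs=1e-10)
    assert unpaired_t(x, y)[0] == pytest.approx(bf_unpaired_t(x, y), abs=1e-10)

    g3 = _random_case(rng, n)
    assert one_way_anova([x, y, g3])[0] == pytest.approx(bf_anova_f([x, y, g3]), abs=1e-10)

    assert coefficient_of_variation([abs(v) + 1 for v in x]) == pytest.approx(
        bf_sd([abs(v) + 1 for v in x]) / bf_mean([abs(v) + 1 for v in x]), abs=1e-12
    )

    ba = bland_altman(x, y)
    d = [a - b for a, b in zip(x, y)]
    assert ba.bias == pytest.approx(bf_mean(d), abs=1e-12)
    assert ba.sd == pytest.approx(bf_sd(d), abs=1e-12)


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.sd == 0.0

    def test_constant_shift(self):
        ba = bland_altman([1, 2, 3], [1.1, 2.1, 3.1])
        assert ba.bias == pytest.approx(-0.1)
        assert ba.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_point_example(self):
        ba = bland_altman([10, 12], [9, 13])
        assert ba.bias == 0.0
        assert ba.sd == pytest.approx(math.sqrt(2), abs=1e-9)
        assert ba.loa_high - ba.loa_low == pytest.approx(4 * ba.sd)

    def test_swapping_arguments_negates_bias(self):
        a, b = [1.0, 4.0, 2.0], [0.5, 5.0, 1.0]
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])


class TestLinearRegression:
    def test_exact_line(self):
        reg = linear_regression([1, 2, 3, 4], [2, 4, 6, 8])
        assert reg.slope == pytest.approx(2.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        reg = linear_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert reg.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        reg = linear_regression([1, 2, 3, 4], [2, 4, 5, 9])
        assert reg.slope == pytest.approx(2.2)
        assert reg.intercept == pytest.approx(-0.5)

    def test_constant_x_rejected(self):
        from suvlean.errors import FitError

        with pytest.raises(FitError):
            linear_regression([2, 2, 2], [1, 2, 3])


class TestTTests:
    def test_paired_hand_example(self):
        t, _ = paired_t([1, 2, 3], [2, 3, 5])
        assert t == pytest.approx(-4.0, abs=1e-9)

    def test_paired_constant_difference_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [2, 3, 4])

    def test_paired_sign_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [2.0, 3.0, 4.0]
        assert paired_t(a, b)[0] == pytest.approx(-paired_t(b, a)[0])

    def test_unpaired_hand_example(self):
        t, _ = unpaired_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=5e-5)

    def test_unpaired_identical_groups(self):
        assert unpaired_t([1, 2, 3], [1, 2, 3])[0] == pytest.approx(0.0)

    def test_unpaired_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 3.0]
        assert unpaired_t(a, b)[0] == pytest.approx(
            unpaired_t([3 * v for v in a], [3 * v for v in b])[0]
        )


class TestAnova:
    def test_two_groups_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.5, 2.2], [2.0, 3.1, 4.0]
        f, pf = one_way_anova([a, b])
        t, pt = unpaired_t(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert pf == pytest.approx(pt, rel=1e-10)

    def test_hand_example(self):
        f, _ = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5)

    def test_identical_groups(self):
        f, _ = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3], [4]])


class TestKsNormal:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(31)
        _, p = ks_normal(rng.standard_normal(1000))
        assert p > 0.05

    def test_two_point_distribution_rejected(self):
        x = [0.0] * 50 + [10.0] * 50
        d, p = ks_normal(x)
        assert p < 0.01
        assert 0.0 <= d <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normal([3.0] * 10)


class TestCv:
    def test_constant_series(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_two_point_example(self):
        assert coefficient_of_variation([2.0, 4.0]) == pytest.approx(0.4714, abs=5e-5)

    def test_scale_invariance(self):
        x = [1.0, 3.0, 7.0]
        assert coefficient_of_variation(x) == pytest.approx(
            coefficient_of_variation([5 * v for v in x]), rel=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestBmiCategorize:
    @pytest.mark.parametrize(
        "bmi,category",
        [
            (23.11, "normal"),
            (18.5, "normal"),  # bin edge goes to the upper category
            (18.49, "underweight"),
            (25.0, "overweight"),
            (32.45, "obese"),
            (30.0, "obese"),
        ],
    )
    def test_bins(self, bmi, category):
        assert bmi_categorize(bmi) == category

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bmi_categorize(0.0)


def _fake_measurements(n, rng, bmi_effect=0.03):
    """Measurement/subject frames where SUVbw carries a BMI slope but the
    lean-normalized columns do not."""
    bmi = rng.uniform(16, 35, size=n)
    subjects = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)], "bmi": bmi})
    rows = []
    for organ in ("liver", "blood"):
        for stat in ("max", "mean"):
            base = rng.uniform(0.8, 1.2)
            noise = rng.normal(0, 0.02, size=n)
            bw = base + bmi_effect * (bmi - bmi.mean()) + noise
            lean = base + noise
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"S{i}",
                        "organ": organ,
                        "statistic": stat,
                        "suv_bw": bw[i],
                        "suv_dixon": lean[i],
                        "suv_james": lean[i] * 1.05,
                        "suv_janma": lean[i] * 0.97,
                    }
                )
    return pd.DataFrame(rows), subjects


class TestReportTables:
    def test_suv_bmi_table_structure_and_pattern(self):
        rng = np.random.default_rng(8)
        meas, subjects = _fake_measurements(30, rng)
        table = build_suv_bmi_table(meas, subjects)
        # organs x statistics x methods rows
        assert len(table) == 2 * 2 * 4
        liver = table[(table.organ == "liver") & (table.statistic == "mean")]
        r_bw = liver.loc[liver.method == "bw", "r_bmi"].item()
        r_dixon = liver.loc[liver.method == "dixon", "r_bmi"].item()
        assert r_bw > r_dixon

    def test_zero_bmi_effect_gives_flat_slopes(self):
        rng = np.random.default_rng(9)
        meas, subjects = _fake_measurements(40, rng, bmi_effect=0.0)
        table = build_suv_bmi_table(meas, subjects)
        assert table["slope_bmi"].abs().max() < 0.01

    def test_subgroup_counts_partition_cohort(self):
        rng = np.random.default_rng(10)
        meas, subjects = _fake_measurements(50, rng)
        table = bmi_subgroup_table(meas, subjects, organ="liver", statistic="mean")
        bw = table[table.method == "bw"]
        assert bw["n"].sum() == 50

    def test_lbm_agreement_bias_sign(self):
        rng = np.random.default_rng(12)
        n = 20
        dxa = rng.uniform(55, 75, size=n)
        df = pd.DataFrame(
            {
                "sex": ["F"] * 10 + ["M"] * 10,
                "frac_dxa": dxa,
                "frac_dixon": dxa + rng.normal(0, 0.5, n),
                "frac_james": dxa + 8 + rng.normal(0, 0.5, n),  # overestimates
                "frac_janma": dxa + 3 + rng.normal(0, 0.5, n),
            }
        )
        table = lbm_agreement_table(df)
        all_rows = table[table.group == "all"].set_index("method")
        assert abs(all_rows.loc["dixon", "bias"]) < 1.0
        assert all_rows.loc["james", "bias"] < -6.0  # reference - test < 0
        assert all_rows.loc["janma", "bias"] < -1.0
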