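"""Agreement/discrimination statistics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from playcog.evaluate import (
    bland_altman_points,
    choose_cutoff,
    error_metrics,
    exposure_bias_test,
    fine_motor_correlation,
    floor_ceiling_analysis,
    icc_2_1,
    pearson_with_ci,
    percentile_cutoff,
    roc_analysis,
)


def icc_2_1_bruteforce(x, y):
    """Independent ICC(2,1) oracle: explicit two-way ANOVA sums of squares."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_subj = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_rater = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_subj = ss_subj / (n - 1)
    ms_rater = ss_rater / (k - 1)
    ms_err = (ss_tot - ss_subj - ss_rater) / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / (
        ms_subj + (k - 1) * ms_err + k * (ms_rater - ms_err) / n
    )


def auc_bruteforce(scores, positive):
    """All-pairs counting oracle: P(score_pos < score_neg), ties half."""
    pos = scores[positive]
    neg = scores[~positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def cutoff_bruteforce(scores, positive):
    """Exhaustive scan over every threshold between adjacent unique scores."""
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best_j, best_t = -np.inf, None
    for t in cands:
        pred = scores < t
        sens = (pred & positive).sum() / positive.sum()
        spec = (~pred & ~positive).sum() / (~positive).sum()
        if sens + spec > best_j + 1e-12:
            best_j, best_t = sens + spec, t
    return best_t


class TestICC:
    def test_identical_vectors(self):
        icc, ci = icc_2_1([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert icc == pytest.approx(1.0)

    def test_hand_anova_example(self):
        # SSsubj=10, SSrater=2, SSerr=0 -> ICC = 10/13
        icc, _ = icc_2_1([1, 2, 3, 4], [2, 3, 4, 5])
        assert icc == pytest.approx(10 / 13, abs=1e-12)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.normal(size=12)
            y = x * rng.uniform(0.2, 2) + rng.normal(scale=0.5, size=12)
            icc, _ = icc_2_1(x, y)
            assert icc == pytest.approx(icc_2_1_bruteforce(x, y), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=0.4, size=15)
        df = pd.DataFrame({
            "s": list(range(15)) * 2, "r": ["a"] * 15 + ["b"] * 15, "v": np.r_[x, y],
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref.Type) else ref.iloc[1]
        icc, ci = icc_2_1(x, y)
        assert icc == pytest.approx(row.ICC, abs=1e-8)
        assert ci[0] == pytest.approx(row.CI95[0], abs=0.01)
        assert ci[1] == pytest.approx(row.CI95[1], abs=0.01)

    def test_zero_between_subject_variance(self):
        with pytest.warns(UserWarning, match="between-subject"):
            icc, _ = icc_2_1([3, 3, 3, 3], [4, 4, 4, 4])
        assert icc == 0.0

    def test_degrades_with_noise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        iccs = [icc_2_1(x, x + rng.normal(scale=s, size=200))[0] for s in (0.0, 0.5, 2.0)]
        assert iccs[0] == pytest.approx(1.0)
        assert iccs[0] > iccs[1] > iccs[2]


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, _ = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_constructed_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)
        r, _ = pearson_with_ci(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_fisher_z_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r, (lo, hi) = pearson_with_ci(x, y)
        z = np.arctanh(r)
        se = 1 / np.sqrt(17)
        assert lo == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + 1.959963984540054 * se), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "deep,bsid,mae,rmse,bias",
        [
            ([1, 2, 3], [1, 2, 3], 0.0, 0.0, 0.0),
            ([3, 1], [1, 3], 2.0, 2.0, 0.0),
            ([2, 3, 4], [1, 1, 1], 2.0, np.sqrt(14 / 3), 2.0),
        ],
    )
    def test_forced_arithmetic(self, deep, bsid, mae, rmse, bias):
        m = error_metrics(deep, bsid)
        assert m["mae"] == pytest.approx(mae)
        assert m["rmse"] == pytest.approx(rmse)
        assert m["bias"] == pytest.approx(bias)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    def test_mae_never_exceeds_rmse(self, errors):
        deep = np.asarray(errors)
        m = error_metrics(deep, np.zeros_like(deep))
        assert m["mae"] <= m["rmse"] + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([], [])


class TestBlandAltman:
    def test_identical_vectors(self):
        _, diffs, (lo, hi) = bland_altman_points([1, 2, 3], [1, 2, 3])
        assert (diffs == 0).all() and lo == hi == 0

    def test_constant_offset(self):
        _, diffs, (lo, hi) = bland_altman_points([4, 5, 6], [1, 2, 3])
        assert (diffs == 3).all() and lo == pytest.approx(3) and hi == pytest.approx(3)

    def test_limits_match_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        _, diffs, (lo, hi) = bland_altman_points(a, b)
        assert lo == pytest.approx(diffs.mean() - 1.96 * diffs.std(ddof=1))
        assert hi == pytest.approx(diffs.mean() + 1.96 * diffs.std(ddof=1))


class TestCutoffAndROC:
    def test_separated_classes_midpoint(self):
        deep = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        positive = deep < 5
        t = choose_cutoff(deep, positive)
        assert 3.0 < t < 10.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            deep = rng.normal(size=12).round(1)
            positive = rng.random(12) < 0.4
            if positive.all() or not positive.any():
                continue
            assert choose_cutoff(deep, positive) == pytest.approx(
                cutoff_bruteforce(deep, positive)
            )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            choose_cutoff([1.0, 2.0], [True, True])

    def test_auc_perfect_and_constant(self):
        bsid = np.array([1, 2, 3, 10, 11, 12.0])
        rep = roc_analysis(bsid, bsid, benchmark_cutoff=5.0, score_cutoff=5.0)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        rep = roc_analysis(np.full(6, 7.0), bsid, 5.0, 5.0)
        assert rep.auc == 0.5

    def test_auc_matches_pair_counting_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        for _ in range(30):
            deep = rng.normal(size=14).round(1)
            bsid = rng.normal(size=14)
            positive = bsid < np.percentile(bsid, 30)
            if positive.all() or not positive.any():
                continue
            rep = roc_analysis(deep, bsid, float(np.percentile(bsid, 30)), 0.0)
            assert rep.auc == pytest.approx(auc_bruteforce(deep, positive))
            assert rep.auc == pytest.approx(roc_auc_score(positive, -deep))


class TestBiasAnalyses:
    def test_identical_groups_t_zero(self):
        errors = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        exposure = np.array([True, True, True, False, False, False])
        t, p, m1, m0 = exposure_bias_test(errors, exposure)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert m1 == m0

    def test_textbook_pooled_variance_formula(self):
        a = np.array([2.1, 3.4, 1.9, 2.8, 3.3])
        b = np.array([1.1, 0.9, 1.8, 1.4])
        errors = np.concatenate([a, b])
        exposure = np.array([True] * 5 + [False] * 4)
        t, p, _, _ = exposure_bias_test(errors, exposure)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(t_hand, abs=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            exposure_bias_test([1.0, 2.0, 3.0], [True, False, False])

    def test_fine_motor_r_squared(self):
        rng = np.random.default_rng(7)
        fmotor = rng.normal(size=300)
        f = fmotor - fmotor.mean()
        noise = rng.normal(size=300)
        noise -= noise.mean()
        noise -= f * (f @ noise) / (f @ f)
        target = -0.25
        errors = target * f / np.linalg.norm(f) + np.sqrt(1 - target**2) * noise / np.linalg.norm(noise)
        r, _, r2 = fine_motor_correlation(errors, fmotor)
        assert r == pytest.approx(-0.25, abs=1e-10)
        assert r2 == pytest.approx(0.0625, abs=1e-10)


class TestFloorCeiling:
    def test_everyone_plays_everything(self):
        bsid = np.arange(60.0, 80.0)
        rep = floor_ceiling_analysis(bsid, np.full(20, 40))
        assert rep.high_not_all_levels == 0
        assert rep.low_below_10_levels == 0

    def test_nine_levels_counts_as_below_ten(self):
        bsid = np.arange(60.0, 80.0)  # 25th-pct cutoff lands at 64
        lp = np.full(20, 40)
        lp[0] = 9    # bsid 60: floor candidate
        lp[1] = 10   # bsid 61: boundary, NOT below 10
        rep = floor_ceiling_analysis(bsid, lp)
        assert rep.n_low == 4
        assert rep.low_below_10_levels == 1  # strict <10

    def test_counts_match_enumeration(self):
        rng = np.random.default_rng(8)
        bsid = rng.integers(57, 89, size=50).astype(float)
        lp = rng.integers(1, 41, size=50)
        rep = floor_ceiling_analysis(bsid, lp)
        lo_cut = percentile_cutoff(bsid, 25)
        hi_cut = percentile_cutoff(bsid, 90)
        assert rep.n_low == int((bsid < lo_cut).sum())
        assert rep.n_high == int((bsid > hi_cut).sum())
        assert rep.low_below_10_levels == int((lp[bsid < lo_cut] < 10).sum())
        assert rep.high_not_all_levels == int((lp[bsid > hi_cut] < 40).sum())
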