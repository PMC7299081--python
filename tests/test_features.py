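"""Featurization oracles: forced arithmetic, imputation rules, pruning,
interaction filters, mas-o-menos and PCA against independent computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from playcog.features import (
    FeatureMatrix,
    FeatureMeta,
    assemble_feature_set,
    build_interactions,
    derive_features,
    extract_raw_features,
    impute_missing,
    mas_o_menos,
    pca_features,
    prune_correlated,
    skew_transform,
)
from tests.conftest import make_session


def toy_matrix(columns: dict[str, list[float]]) -> FeatureMatrix:
    values = pd.DataFrame(columns, index=[f"c{i}" for i in range(len(next(iter(columns.values()))))])
    meta = {n: FeatureMeta(n, "ms", None, "accuracy_cbyi", "derived") for n in values.columns}
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return FeatureMatrix(values, meta, mask)


class TestExtraction:
    def test_counts_and_first_correct_timestamp(self, schema, toy_sessions):
        fm = extract_raw_features(toy_sessions, schema)
        row = fm.values.loc["k1"]
        assert row["st_l1_correctclicks"] == 2
        assert row["st_l1_incorrectclicks"] == 1
        assert row["st_l1_backgroundevents"] == 0
        assert row["st_l1_latency"] == 500
        assert row["at_l1_backgroundevents"] == 1
        assert row["at_l1_latency"] == 2100

    def test_attempted_level_with_zero_events(self, schema):
        fm = extract_raw_features([make_session("k", "st", 1, [])], schema)
        row = fm.values.loc["k"]
        assert row["st_l1_correctclicks"] == 0
        assert np.isnan(row["st_l1_latency"])
        assert fm.mask.loc["k", "st_l1_latency"]

    def test_unattempted_level_fully_masked(self, schema, toy_sessions):
        fm = extract_raw_features(toy_sessions, schema)
        st2 = [c for c in fm.names if c.startswith("st_l2_")]
        assert fm.mask.loc["k1", st2].all()


class TestDerivation:
    def test_accuracy_arithmetic(self, schema):
        events = [(100 * i, "tap", "correct") for i in range(1, 4)] + [(500, "tap", "incorrect")]
        fm = derive_features(extract_raw_features(
            [make_session("k", "st", 1, sorted(events))], schema), schema)
        row = fm.values.loc["k"]
        assert row["st_l1_accuracy_cbyi"] == pytest.approx(0.75)
        assert row["st_l1_accuracy_cbyt"] == pytest.approx(0.75)

    def test_correctrate_per_second(self, schema):
        events = [(0, "tap", "correct"), (5000, "tap", "correct"), (10000, "tap", "correct")]
        fm = derive_features(extract_raw_features(
            [make_session("k", "st", 1, events)], schema), schema)
        assert fm.values.loc["k", "st_l1_correctrate"] == pytest.approx(0.3)
        assert fm.values.loc["k", "st_l1_playtime"] == pytest.approx(10.0)

    def test_levels_played_count(self, small_cohort, schema):
        fm = derive_features(extract_raw_features(small_cohort.sessions, schema), schema)
        lp = small_cohort.levels_played()
        assert np.array_equal(
            fm.values.loc[small_cohort.child_ids, "sum_all_levels_played"].to_numpy(), lp
        )


class TestImputation:
    def test_missed_level_rules(self, schema, toy_sessions):
        fm = impute_missing(derive_features(
            extract_raw_features(toy_sessions, schema), schema), schema)
        row = fm.values.loc["k1"]
        assert row["st_l2_accuracy_cbyi"] == 0.0
        assert row["st_l2_correctrate"] == 0.0
        assert row["st_l2_completion_time"] == 60.0   # the level timer
        assert row["st_l2_latency"] == 60_000
        assert row["st_l2_correctclicks"] == 0.0
        assert not fm.values.isna().any().any()

    def test_mask_preserved(self, schema, toy_sessions):
        fm = impute_missing(derive_features(
            extract_raw_features(toy_sessions, schema), schema), schema)
        assert fm.mask.loc["k1", "st_l2_accuracy_cbyi"]
        assert not fm.mask.loc["k1", "st_l1_accuracy_cbyi"]

    def test_fully_played_child_unchanged(self, schema):
        sessions = []
        for g in schema.games:
            for lvl in range(1, g.n_levels + 1):
                ev = [(1000 * i, "tap" if g.gesture != "drag" else "drag", "correct")
                      for i in range(1, g.advance_threshold + 1)]
                sessions.append(make_session("k", g.game_id, lvl, ev, completed=True))
        derived = derive_features(extract_raw_features(sessions, schema), schema)
        imputed = impute_missing(derived, schema)
        pd.testing.assert_frame_equal(derived.values, imputed.values)

    def test_aggregates_use_filled_values(self, schema, toy_sessions):
        fm = impute_missing(derive_features(
            extract_raw_features(toy_sessions, schema), schema), schema)
        # 38 unattempted levels at 60 s + two attempted st/at level-1 sessions
        expected = 38 * 60.0 + 60.0 + 60.0  # neither attempted level was completed
        assert fm.values.loc["k1", "sum_completion_time"] == pytest.approx(expected)


class TestSkewTransform:
    def test_symmetric_column_unchanged(self):
        fm = toy_matrix({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out, log = skew_transform(fm)
        assert log == {}
        assert out.names == ["a"]

    def test_right_skew_gets_sqrt(self):
        col = [0.0] * 9 + [10.0]
        assert stats.skew(col, bias=False) > 1  # oracle: adjusted Fisher-Pearson
        out, log = skew_transform(toy_matrix({"a": col}))
        assert log == {"a": "sqrt"}
        assert out.names == ["a_sqrt"]
        assert out.meta["a_sqrt"].transform == "sqrt"
        np.testing.assert_allclose(out.values["a_sqrt"], np.sqrt(col))

    def test_left_skew_gets_square_by_symmetry(self):
        col = [0.0] * 9 + [10.0]
        mirrored = [-c for c in col]
        out, log = skew_transform(toy_matrix({"a": mirrored}))
        assert log == {"a": "square"}
        np.testing.assert_allclose(out.values["a_sq"], np.square(mirrored))

    def test_negative_minimum_shifted_before_sqrt(self):
        col = [-1.0] * 9 + [9.0]
        out, _ = skew_transform(toy_matrix({"a": col}))
        assert (out.values["a_sqrt"] >= 0).all()
        np.testing.assert_allclose(out.values["a_sqrt"], np.sqrt(np.array(col) + 1.0))


class TestPruning:
    def test_duplicate_dropped_orthogonal_kept(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        fm = toy_matrix({"a": a, "dup": a * 2 + 1, "b": b})
        out = prune_correlated(fm)
        assert out.names == ["a", "b"]

    def test_survivors_pairwise_below_threshold(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        cols = {f"f{i}": base * w + rng.normal(scale=s, size=200)
                for i, (w, s) in enumerate([(1, 0.1), (1, 0.1), (0.3, 1.0), (0, 1.0), (1, 0.05)])}
        out = prune_correlated(toy_matrix(cols), r_max=0.9)
        surv = out.values.to_numpy()
        corr = np.corrcoef(surv, rowvar=False)
        for i in range(corr.shape[0]):           # brute-force all-pairs oracle
            for j in range(i + 1, corr.shape[0]):
                assert abs(corr[i, j]) <= 0.9

    def test_zero_variance_retained_with_warning(self):
        fm = toy_matrix({"a": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            out = prune_correlated(fm)
        assert "const" in out.names


class TestInteractions:
    def test_two_feature_subset_yields_three_candidates(self):
        rng = np.random.default_rng(2)
        fm = toy_matrix({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        out = build_interactions(fm, ["a", "b"], r_max=1.1)  # disable corr filter
        new = set(out.names) - {"a", "b"}
        assert new == {"a_times_b", "a_div_by_b", "b_div_by_a"}

    def test_ratio_with_many_zero_denominators_excluded(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=40)
        b[:8] = 0.0  # 20% undefined
        fm = toy_matrix({"a": rng.normal(size=40), "b": b})
        out = build_interactions(fm, ["a", "b"], r_max=1.1)
        assert "a_div_by_b" not in out.names
        assert "b_div_by_a" in out.names

    def test_correlated_candidate_excluded(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=60)
        fm = toy_matrix({"a": a, "pos": np.exp(rng.normal(size=60))})
        out = build_interactions(fm, ["a", "pos"])
        # a * pos correlates strongly with a, ratio columns checked pairwise
        surv = out.values.to_numpy()
        corr = np.abs(np.corrcoef(surv, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9 + 1e-12

    def test_absent_subset_member_raises(self):
        fm = toy_matrix({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(KeyError, match="zzz"):
            build_interactions(fm, ["a", "zzz"])


class TestMasOMenos:
    def test_hand_computed_three_columns(self):
        X = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [4.0, 3.0, 2.0, 1.0], "c": [1.0, 3.0, 2.0, 4.0]},
            index=list("wxyz"),
        )
        y = [10.0, 20.0, 30.0, 40.0]
        score, w = mas_o_menos(X, y, X)
        # oracle: standardize each column, weight by sign of corr with y
        Z = (X - X.mean()) / X.std(ddof=0)
        expected = (Z["a"] * 1 + Z["b"] * -1 + Z["c"] * 1) / 3
        np.testing.assert_allclose(score, expected)
        assert list(w) == [1.0, -1.0, 1.0]

    def test_duplicated_column_idempotent(self):
        rng = np.random.default_rng(5)
        a = pd.Series(rng.normal(size=30))
        y = a + rng.normal(scale=0.1, size=30)
        X1 = pd.DataFrame({"a": a})
        X2 = pd.DataFrame({"a": a, "a2": a})
        s1, _ = mas_o_menos(X1, y, X1)
        s2, _ = mas_o_menos(X2, y, X2)
        np.testing.assert_allclose(s1, s2)

    def test_zero_variance_column_excluded(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "const": [7.0] * 4})
        y = [1.0, 2.0, 3.0, 4.0]
        score, w = mas_o_menos(X, y, X)
        assert w["const"] == 0.0
        Z = (X["a"] - X["a"].mean()) / X["a"].std(ddof=0)
        np.testing.assert_allclose(score, Z)


class TestPCA:
    def test_perfectly_correlated_pair_needs_one_component(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a + 3})
        scores, _ = pca_features(X, X, var_target=0.99)
        assert scores.shape[1] == 1

    def test_isotropic_noise_needs_three_of_four(self):
        # eigenvalue oracle: ~25% variance per component -> 3 reach 70%
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        Z = (X - X.mean()) / X.std(ddof=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Z.to_numpy(), rowvar=False)))[::-1]
        k_oracle = int(np.searchsorted(np.cumsum(evals / evals.sum()), 0.70) + 1)
        scores, _ = pca_features(X, X, var_target=0.70)
        assert scores.shape[1] == k_oracle == 3

    def test_identical_rows_identical_scores(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        s1, _ = pca_features(X, X.iloc[:10], var_target=0.7)
        s2, _ = pca_features(X, X.iloc[:10], var_target=0.7)
        pd.testing.assert_frame_equal(s1, s2)


class TestAssembly:
    def test_bookkeeping_identity_and_determinism(self, small_cohort):
        fm1, rep1 = assemble_feature_set(small_cohort)
        fm2, rep2 = assemble_feature_set(small_cohort)
        assert rep1 == rep2
        pd.testing.assert_frame_equal(fm1.values, fm2.values)
        assert rep1["final"] == rep1["pruned_set"] + rep1["interactions"] + 1 + rep1["pca"]
        assert rep1["final"] == len(fm1.names)

    def test_no_test_row_leakage(self, small_cohort):
        """Fitted transforms depend only on training rows: perturbing held-out
        children never changes training-row feature values."""
        ids = small_cohort.child_ids
        fit_ids = ids[:28]
        fm_full, _ = assemble_feature_set(small_cohort, fit_ids=fit_ids)

        # rebuild a cohort whose held-out children's outcomes are shuffled
        import copy

        mutated = copy.deepcopy(small_cohort)
        held = [c for c in mutated.children if c.child_id not in fit_ids]
        scores = [c.bsid_cognitive_raw for c in held]
        for c, s in zip(held, scores[::-1]):
            c.bsid_cognitive_raw = s
        fm_mut, _ = assemble_feature_set(mutated, fit_ids=fit_ids)
        pd.testing.assert_frame_equal(
            fm_full.values.loc[fit_ids], fm_mut.values.loc[fit_ids]
        )
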