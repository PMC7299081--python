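"""Stacked-ensemble scoring model.

The learning machinery: a 70/30 train/test split, repeated k-fold
cross-validation over a grid of feature selectors x learners, ranking of
the grid by out-of-fold correlation with the benchmark score, refitting
of the top five models on the full training set, three stacking
meta-learners (linear regression, random forest, gradient boosting)
fitted on the out-of-fold base predictions, and a fixed 0.25/0.25/0.50
weighted average of the three stacked predictions — the final "DEEP"
score for each child.

Surface: :class:`DeepScoreModel` (construct from a cohort or a feature
matrix) whose :meth:`~DeepScoreModel.fit` returns
:class:`DeepScoreResults` carrying predictions, the top-5 manifest and a
``summary()`` table.  The underlying steps are importable functions
(:func:`split_train_test`, :func:`run_repeated_cv`,
:func:`rank_and_select`, :func:`build_ensemble`,
:func:`predict_deep_scores`) for composition and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression, LogisticRegression, enet_path, lasso_path
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import FeatureConfig, FeatureMatrix, assemble_feature_set
from .simulate import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "ModelResult",
    "EnsembleModel",
    "DeepScoreModel",
    "DeepScoreResults",
    "split_train_test",
    "run_repeated_cv",
    "rank_and_select",
    "build_ensemble",
    "predict_deep_scores",
    "SELECTORS",
    "LEARNERS",
]


@dataclass
class CVConfig:
    """Cross-validation and ensembling configuration."""

    train_fraction: float = 0.70
    k_folds: int = 10
    repeats: int = 10
    seed: int = 0
    selector_cap: int = 15
    n_top_models: int = 5
    stack_weights: tuple[float, float, float] = (0.25, 0.25, 0.50)
    selectors: tuple[str, ...] = (
        "univariate_corr", "lasso", "elastic_net", "rf_importance",
        "gb_importance", "rfe_linear", "mrmr",
    )
    learners: tuple[str, ...] = (
        "linear_regression", "random_forest", "svm", "xgboost", "logistic_regression",
    )
    support: tuple[int, int] = (57, 88)

    def validate(self) -> None:
        if abs(sum(self.stack_weights) - 1.0) > 1e-12:
            raise ValueError("stack_weights must sum to 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.selector_cap < 1:
            raise ValueError("selector_cap must be >= 1")
        unknown = set(self.selectors) - set(SELECTORS)
        if unknown:
            raise ValueError(f"unknown selector(s): {sorted(unknown)}")
        unknown = set(self.learners) - set(LEARNERS)
        if unknown:
            raise ValueError(f"unknown learner(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# selector registry: (X, y, cap, seed) -> list of feature names, len <= cap


def _univariate_corr(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
    sd = X.std(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(
            ((X - X.mean(axis=0)).to_numpy().T @ (y - y.mean()))
            / (len(y) * sd * y.std())
        )
    r = np.where(sd > 0, np.nan_to_num(r), 0.0)
    order = np.argsort(-r, kind="stable")[:cap]
    return [X.columns[i] for i in order]


def _path_selector(path_fn) -> Callable:
    def select(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = path_fn(X.to_numpy(), y, n_alphas=30, eps=1e-2, tol=1e-3)
        nnz = (coefs != 0).sum(axis=0)  # alphas ordered large -> small
        ok = np.flatnonzero(nnz <= cap)
        best = ok[np.argmax(nnz[ok])] if len(ok) else 0
        names = [X.columns[i] for i in np.flatnonzero(coefs[:, best])]
        if not names:
            return _univariate_corr(X, y, cap, seed)
        return names

    return select


def _rf_importance(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
    rf = RandomForestRegressor(
        n_estimators=80, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(X.to_numpy(), y)
    order = np.argsort(-rf.feature_importances_, kind="stable")[:cap]
    return [X.columns[i] for i in order]


def _gb_importance(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
    gb = XGBRegressor(
        n_estimators=80, max_depth=3, learning_rate=0.15, random_state=seed,
        n_jobs=1, tree_method="hist", verbosity=0,
    )
    gb.fit(X.to_numpy(), y)
    order = np.argsort(-gb.feature_importances_, kind="stable")[:cap]
    return [X.columns[i] for i in order]


def _rfe_linear(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
    rfe = RFE(LinearRegression(), n_features_to_select=cap, step=0.25)
    rfe.fit(X.to_numpy(), y)
    return [X.columns[i] for i in np.flatnonzero(rfe.support_)]


def _mrmr(X: pd.DataFrame, y: np.ndarray, cap: int, seed: int) -> list[str]:
    """Greedy minimum-redundancy-maximum-relevance on Pearson correlations."""
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    Z = (Xv - mu) / np.where(sd > 0, sd, 1.0)
    yz = (y - y.mean()) / (y.std() or 1.0)
    rel = np.abs(Z.T @ yz / len(y))
    rel[sd == 0] = 0.0
    selected = [int(np.argmax(rel))]
    redundancy = np.abs(Z.T @ Z[:, selected[0]] / len(y))
    while len(selected) < min(cap, Xv.shape[1]):
        score = rel - redundancy / len(selected)
        score[selected] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]):
            break
        selected.append(j)
        redundancy += np.abs(Z.T @ Z[:, j] / len(y))
    return [X.columns[i] for i in selected]


SELECTORS: dict[str, Callable] = {
    "univariate_corr": _univariate_corr,
    "lasso": _path_selector(lasso_path),
    "elastic_net": _path_selector(enet_path),
    "rf_importance": _rf_importance,
    "gb_importance": _gb_importance,
    "rfe_linear": _rfe_linear,
    "mrmr": _mrmr,
}


# ---------------------------------------------------------------------------
# learner registry: factory(seed, support) -> estimator with fit/predict


class _LogisticScorer:
    """Score regression through a classifier.

    The outcome is dichotomized at the training 25th percentile; the
    fitted probability of scoring *above* that threshold is rescaled
    linearly onto the score support, so the contribution behaves like the
    other score predictors.
    """

    def __init__(self, seed: int, support: tuple[int, int]):
        self.support = support
        self.clf = LogisticRegression(max_iter=2000, random_state=seed)
        self.constant_: float | None = None

    def fit(self, X, y):
        cutoff = np.percentile(y, 25)
        labels = (y > cutoff).astype(int)
        if labels.min() == labels.max():
            self.constant_ = float(np.mean(y))
            return self
        self.clf.fit(X, labels)
        return self

    def predict(self, X):
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        lo, hi = self.support
        p = self.clf.predict_proba(X)[:, 1]
        return lo + p * (hi - lo)


LEARNERS: dict[str, Callable] = {
    "linear_regression": lambda seed, support: LinearRegression(),
    "random_forest": lambda seed, support: RandomForestRegressor(
        n_estimators=100, random_state=seed, n_jobs=1
    ),
    "svm": lambda seed, support: SVR(kernel="rbf", C=10.0, gamma="scale"),
    "xgboost": lambda seed, support: XGBRegressor(
        n_estimators=150, max_depth=3, learning_rate=0.1, subsample=0.9,
        colsample_bytree=0.9, random_state=seed, n_jobs=1, tree_method="hist",
        verbosity=0,
    ),
    "logistic_regression": _LogisticScorer,
}


# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    """One selector x learner cell of the CV grid."""

    selector: str
    learner: str
    out_of_fold_predictions: pd.Series
    holdout_correlation: float
    n_features: float          # mean per-fold selected-set size (tie-break)
    failed: bool = False

    @property
    def name(self) -> str:
        return f"{self.selector}|{self.learner}"


@dataclass
class EnsembleModel:
    """Top-5 base models + 3 stackers + fixed weights."""

    base_models: list[dict]            # selector, learner, features, estimator
    stackers: dict[str, object]        # linear_regression, random_forest, xgboost
    weights: tuple[float, float, float]
    support: tuple[int, int]
    oof_matrix: pd.DataFrame           # n_train x 5 out-of-fold base predictions
    train_ids: list[str]

    def __post_init__(self) -> None:
        assert len(self.base_models) == 5, "ensemble requires exactly 5 base models"
        assert len(self.stackers) == 3, "ensemble requires exactly 3 stackers"

    def contributing_games(self, game_ids: Sequence[str]) -> set[str]:
        """Games whose whole-game absence makes a child unpredictable."""
        games: set[str] = set()
        for bm in self.base_models:
            for scope in bm["scopes"]:
                games |= _scope_games(scope, game_ids)
        return games


def _scope_games(scope: str, game_ids: Sequence[str]) -> set[str]:
    """Decode a FeatureMeta game_scope into the set of games it touches."""
    if scope == "across":
        return set()
    out: set[str] = set()
    for token in scope.split("+"):
        if token in game_ids:
            out.add(token)
            continue
        # concatenated pair code, e.g. "msjig"
        rest = token
        while rest:
            for gid in sorted(game_ids, key=len, reverse=True):
                if rest.startswith(gid):
                    out.add(gid)
                    rest = rest[len(gid):]
                    break
            else:
                break  # not decodable (e.g. "across" fragments) -> ignore
    return out


class _MeanPredictor:
    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


# ---------------------------------------------------------------------------
# operations


def split_train_test(
    child_ids: Sequence[str] | Cohort, cv: CVConfig
) -> tuple[list[str], list[str]]:
    """Random 70/30 split by seed; proportions within one child of exact."""
    if isinstance(child_ids, Cohort):
        child_ids = child_ids.child_ids
    ids = list(child_ids)
    if len(ids) < 10:
        raise ValueError(f"cohort of {len(ids)} too small to split (need >= 10)")
    rng = np.random.default_rng(cv.seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(cv.train_fraction * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def run_repeated_cv(
    fm_train: pd.DataFrame,
    y_train: pd.Series,
    cv: CVConfig,
) -> list[ModelResult]:
    """Repeated k-fold CV over the selector x learner grid.

    Selectors run once per fold on the training folds (so every learner in
    a fold sees the same selected set); out-of-fold predictions are
    averaged over repeats; each grid cell's holdout correlation is the
    Pearson r between those averaged predictions and the outcome.
    """
    cv.validate()
    ids = list(fm_train.index)
    y = y_train.loc[ids].to_numpy(dtype=float)
    grid = [(s, l) for s in cv.selectors for l in cv.learners]
    pred_sum = {g: np.zeros(len(ids)) for g in grid}
    pred_cnt = {g: np.zeros(len(ids)) for g in grid}
    nfeat = {s: [] for s in cv.selectors}
    failed = {g: False for g in grid}

    for rep in range(cv.repeats):
        kf = KFold(n_splits=cv.k_folds, shuffle=True, random_state=cv.seed + rep)
        for fold, (tr, ho) in enumerate(kf.split(ids)):
            Xtr, Xho = fm_train.iloc[tr], fm_train.iloc[ho]
            ytr = y[tr]
            fold_seed = cv.seed + 1000 * rep + fold
            for sel in cv.selectors:
                try:
                    feats = SELECTORS[sel](Xtr, ytr, cv.selector_cap, fold_seed)
                except Exception as exc:  # selector failure fails its column
                    logger.warning("selector %s failed on rep %d fold %d: %s", sel, rep, fold, exc)
                    for lrn in cv.learners:
                        failed[(sel, lrn)] = True
                    continue
                assert len(feats) <= cv.selector_cap
                nfeat[sel].append(len(feats))
                Xs, Xh = Xtr[feats].to_numpy(), Xho[feats].to_numpy()
                for lrn in cv.learners:
                    try:
                        est = LEARNERS[lrn](fold_seed, cv.support)
                        est.fit(Xs, ytr)
                        p = np.asarray(est.predict(Xh), dtype=float)
                    except Exception as exc:
                        logger.warning("learner %s/%s failed: %s", sel, lrn, exc)
                        failed[(sel, lrn)] = True
                        continue
                    pred_sum[(sel, lrn)][ho] += p
                    pred_cnt[(sel, lrn)][ho] += 1

    results = []
    for (sel, lrn) in grid:
        cnt = pred_cnt[(sel, lrn)]
        bad = failed[(sel, lrn)] or (cnt == 0).any()
        if bad:
            oof = pd.Series(np.nan, index=ids)
            r = -np.inf
        else:
            oof = pd.Series(pred_sum[(sel, lrn)] / cnt, index=ids)
            r = _safe_pearson(oof.to_numpy(), y)
        results.append(
            ModelResult(
                selector=sel,
                learner=lrn,
                out_of_fold_predictions=oof,
                holdout_correlation=r,
                n_features=float(np.mean(nfeat[sel])) if nfeat[sel] else np.nan,
                failed=bad,
            )
        )
    return results


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rank_and_select(results: Sequence[ModelResult], cv: CVConfig) -> list[ModelResult]:
    """Top models by holdout correlation; ties -> fewer features, then name."""
    viable = [r for r in results if not r.failed]
    if len(viable) < cv.n_top_models:
        raise ValueError(
            f"only {len(viable)} viable models; need {cv.n_top_models} — "
            "enlarge the selector/learner grid"
        )
    ranked = sorted(viable, key=lambda r: (-r.holdout_correlation, r.n_features, r.name))
    return ranked[: cv.n_top_models]


def build_ensemble(
    top: Sequence[ModelResult],
    fm_train: pd.DataFrame,
    y_train: pd.Series,
    cv: CVConfig,
) -> EnsembleModel:
    """Refit the top-5 on the full training set and fit the three stackers
    on their out-of-fold predictions."""
    ids = list(fm_train.index)
    y = y_train.loc[ids].to_numpy(dtype=float)
    oof = pd.DataFrame(
        {f"{i + 1}:{r.name}": r.out_of_fold_predictions.loc[ids] for i, r in enumerate(top)}
    )

    base_models = []
    for r in top:
        feats = SELECTORS[r.selector](fm_train, y, cv.selector_cap, cv.seed)
        est = LEARNERS[r.learner](cv.seed, cv.support)
        est.fit(fm_train[feats].to_numpy(), y)
        scopes = set()
        base_models.append(
            {"selector": r.selector, "learner": r.learner, "features": feats,
             "estimator": est, "scopes": scopes, "cv_correlation": r.holdout_correlation}
        )

    D = oof.to_numpy(dtype=float)
    stackers: dict[str, object] = {}
    degenerate = D.std(axis=0).max() == 0
    specs = _stacker_specs(cv.seed)
    for name, make in specs.items():
        if degenerate:
            warnings.warn("constant base predictions; stacker falls back to the mean")
            stackers[name] = _MeanPredictor(y.mean())
        else:
            stackers[name] = make().fit(D, y)

    return EnsembleModel(
        base_models=base_models,
        stackers=stackers,
        weights=cv.stack_weights,
        support=cv.support,
        oof_matrix=oof,
        train_ids=ids,
    )


def _stacker_specs(seed: int) -> dict[str, Callable]:
    return {
        "linear_regression": lambda: LinearRegression(),
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=100, max_depth=4, min_samples_leaf=5,
            random_state=seed, n_jobs=1,
        ),
        "xgboost": lambda: XGBRegressor(
            n_estimators=60, max_depth=2, learning_rate=0.1, subsample=0.9,
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0,
        ),
    }


def _stacked_scores(model: EnsembleModel, D: np.ndarray, index) -> pd.Series:
    w = model.weights
    parts = [
        np.asarray(model.stackers[name].predict(D), dtype=float)
        for name in ("linear_regression", "random_forest", "xgboost")
    ]
    deep = w[0] * parts[0] + w[1] * parts[1] + w[2] * parts[2]
    lo, hi = model.support
    return pd.Series(np.clip(deep, lo, hi), index=index, name="deep_score")


def predict_deep_scores(
    model: EnsembleModel,
    fm: pd.DataFrame | FeatureMatrix,
    attempted_games: dict[str, set[str]] | None = None,
    game_ids: Sequence[str] = (),
) -> tuple[pd.Series, list[str]]:
    """Final scores = 0.25*stack_LR + 0.25*stack_RF + 0.50*stack_XGB.

    Children missing an entire game that contributes any final-model
    feature are excluded and listed rather than imputed.  Returns
    (scores, excluded child ids).
    """
    values = fm.values if isinstance(fm, FeatureMatrix) else fm
    excluded: list[str] = []
    if attempted_games is not None:
        needed = model.contributing_games(game_ids)
        excluded = [
            cid for cid in values.index if needed - attempted_games.get(cid, set())
        ]
    keep = [cid for cid in values.index if cid not in set(excluded)]
    if not keep:
        raise ValueError("all children excluded from prediction")
    rows = values.loc[keep]
    D = np.column_stack(
        [
            np.asarray(bm["estimator"].predict(rows[bm["features"]].to_numpy()), dtype=float)
            for bm in model.base_models
        ]
    )
    return _stacked_scores(model, D, rows.index), excluded


def train_deep_scores(
    model: EnsembleModel, y_train: pd.Series, seed: int = 0, k_folds: int = 10
) -> pd.Series:
    """Training-set scores with the stacker stage also cross-validated.

    The base-model inputs are already out-of-fold; refitting the stackers
    per fold and predicting only held-out rows keeps the reported training
    performance honest (otherwise the gradient-boosted stacker's in-sample
    fit would inflate it).
    """
    D = model.oof_matrix.to_numpy(dtype=float)
    y = y_train.loc[model.oof_matrix.index].to_numpy(dtype=float)
    if D.std(axis=0).max() == 0:
        return _stacked_scores(model, D, model.oof_matrix.index)
    specs = _stacker_specs(seed)
    out = np.empty(len(D))
    kf = KFold(n_splits=min(k_folds, len(D)), shuffle=True, random_state=seed)
    w = model.weights
    for tr, ho in kf.split(D):
        parts = [
            np.asarray(make().fit(D[tr], y[tr]).predict(D[ho]), dtype=float)
            for make in specs.values()
        ]
        out[ho] = w[0] * parts[0] + w[1] * parts[1] + w[2] * parts[2]
    lo, hi = model.support
    return pd.Series(np.clip(out, lo, hi), index=model.oof_matrix.index, name="deep_score")


# ---------------------------------------------------------------------------
# model / results surface


class DeepScoreModel:
    """Gameplay-features -> benchmark-score model.

    Parameters
    ----------
    features : FeatureMatrix
        Fully assembled (imputed, transformed, scaled) feature matrix for
        all children.
    y : pd.Series
        Benchmark cognitive raw score indexed by child_id.
    cv : CVConfig
    train_ids, test_ids : the 70/30 split (see :func:`split_train_test`).
    attempted_games : per-child set of attempted games, for the
        prediction-exclusion rule.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        y: pd.Series,
        cv: CVConfig | None = None,
        train_ids: Sequence[str] | None = None,
        test_ids: Sequence[str] | None = None,
        attempted_games: dict[str, set[str]] | None = None,
        game_ids: Sequence[str] = (),
    ):
        self.features = features
        self.y = y.astype(float)
        self.cv = cv or CVConfig()
        self.cv.validate()
        if train_ids is None:
            train_ids, test_ids = split_train_test(list(features.child_ids), self.cv)
        self.train_ids = list(train_ids)
        self.test_ids = list(test_ids or [])
        self.attempted_games = attempted_games
        self.game_ids = tuple(game_ids)
        self.cohort: Cohort | None = None
        self.feature_report: dict | None = None

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        cv: CVConfig | None = None,
        feature_config: FeatureConfig | None = None,
        paperlike: bool = False,
    ) -> "DeepScoreModel":
        """Split, then assemble features with all data-dependent fits on
        the training rows (or on everything when ``paperlike``)."""
        cv = cv or CVConfig()
        cv.validate()
        train_ids, test_ids = split_train_test(cohort.child_ids, cv)
        fm, report = assemble_feature_set(
            cohort, feature_config, fit_ids=None if paperlike else train_ids
        )
        y = pd.Series(
            {c.child_id: float(c.bsid_cognitive_raw) for c in cohort.children}
        )
        attempted = {
            cid: {s.game_id for s in sess if s.attempted}
            for cid, sess in cohort.sessions_by_child().items()
        }
        obj = cls(
            fm, y, cv, train_ids, test_ids,
            attempted_games=attempted, game_ids=cohort.schema.game_ids,
        )
        obj.feature_report = report
        obj.cohort = cohort
        return obj

    def fit(self) -> "DeepScoreResults":
        Xtr = self.features.values.loc[self.train_ids]
        ytr = self.y.loc[self.train_ids]
        cv_results = run_repeated_cv(Xtr, ytr, self.cv)
        top = rank_and_select(cv_results, self.cv)
        ensemble = build_ensemble(top, Xtr, ytr, self.cv)
        for bm in ensemble.base_models:
            bm["scopes"] = {self.features.meta[f].game_scope for f in bm["features"]}
        return DeepScoreResults(self, cv_results, top, ensemble)


class DeepScoreResults:
    """Fitted ensemble: predictions, manifest, summary, evaluation hooks."""

    def __init__(
        self,
        model: DeepScoreModel,
        cv_results: list[ModelResult],
        top: list[ModelResult],
        ensemble: EnsembleModel,
    ):
        self.model = model
        self.cv_results = cv_results
        self.top = top
        self.ensemble = ensemble
        self.train_scores = train_deep_scores(
            ensemble, model.y, seed=model.cv.seed, k_folds=model.cv.k_folds
        )
        if model.test_ids:
            fm_test = model.features.values.loc[model.test_ids]
            self.test_scores, self.excluded_test = predict_deep_scores(
                ensemble, fm_test, model.attempted_games, model.game_ids
            )
        else:
            self.test_scores, self.excluded_test = pd.Series(dtype=float), []

    @property
    def manifest(self) -> pd.DataFrame:
        """Top-5 manifest: selector, learner, CV correlation, features."""
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "selector": bm["selector"],
                    "learner": bm["learner"],
                    "cv_correlation": bm["cv_correlation"],
                    "n_features": len(bm["features"]),
                    "features": ";".join(bm["features"]),
                }
                for i, bm in enumerate(self.ensemble.base_models)
            ]
        )

    @property
    def selected_features(self) -> list[str]:
        """Unique features across the five base models."""
        seen: dict[str, None] = {}
        for bm in self.ensemble.base_models:
            for f in bm["features"]:
                seen.setdefault(f)
        return list(seen)

    def grid_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "selector": r.selector, "learner": r.learner,
                    "cv_correlation": r.holdout_correlation,
                    "mean_n_features": r.n_features, "failed": r.failed,
                }
                for r in self.cv_results
            ]
        ).sort_values("cv_correlation", ascending=False, ignore_index=True)

    def evaluate(self, paperlike_percentile: bool = False):
        """Full agreement / ROC / bias evaluation (train and test)."""
        from .evaluate import evaluate_results

        return evaluate_results(self, paperlike_percentile=paperlike_percentile)

    def summary(self) -> str:
        y = self.model.y
        lines = [
            "Stacked ensemble score model",
            "============================",
            f"children: {len(y)} (train {len(self.model.train_ids)}, "
            f"test {len(self.model.test_ids)}; {len(self.excluded_test)} test exclusion(s))",
            f"grid: {len(self.model.cv.selectors)} selectors x "
            f"{len(self.model.cv.learners)} learners, "
            f"{self.model.cv.repeats}x{self.model.cv.k_folds}-fold CV",
            f"stack weights (LR, RF, XGB): {self.model.cv.stack_weights}",
            "",
            "top-5 base models:",
        ]
        for _, row in self.manifest.iterrows():
            lines.append(
                f"  {row['rank']}. {row.selector} + {row.learner}: "
                f"r_cv = {row.cv_correlation:.3f} ({row.n_features} features)"
            )
        ytr = y.loc[self.train_scores.index].to_numpy()
        lines.append("")
        lines.append(
            f"train r(DEEP, benchmark) = {_safe_pearson(self.train_scores.to_numpy(), ytr):.3f}"
        )
        if len(self.test_scores):
            yte = y.loc[self.test_scores.index].to_numpy()
            lines.append(
                f"test  r(DEEP, benchmark) = {_safe_pearson(self.test_scores.to_numpy(), yte):.3f}"
            )
        return "\n".join(lines)
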