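"""Agreement, discrimination and bias evaluation of predicted scores.

Implements the full performance surface for a score-prediction method
benchmarked against a reference instrument:

* agreement — Pearson r with Fisher-z CI, ICC(2,1) (two-way random
  effects, absolute agreement, single measures) with the F-based CI,
  error metrics (MAE, RMSE, mean bias) and Bland-Altman limits;
* discrimination — ROC analysis for identifying children below the 25th
  percentile of the benchmark, with a Youden-style training cutoff;
* bias — an equal-variance t-test of prediction errors by prior
  touchscreen exposure, and the correlation of errors with the fine-motor
  score;
* floor/ceiling — levels-played distributions of the lowest (<25th
  percentile) and highest (>90th percentile) benchmark scorers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "ROCReport",
    "BiasReport",
    "FloorCeilingReport",
    "EvaluationBundle",
    "icc_2_1",
    "pearson_with_ci",
    "error_metrics",
    "bland_altman_points",
    "percentile_cutoff",
    "choose_cutoff",
    "roc_analysis",
    "exposure_bias_test",
    "fine_motor_correlation",
    "floor_ceiling_analysis",
    "evaluate_results",
]


# ---------------------------------------------------------------------------
# agreement


def icc_2_1(x: Sequence[float], y: Sequence[float], alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``x`` and ``y`` are the two "raters" (here the two scoring methods)
    over the same subjects.  Estimate and CI follow the standard
    mean-squares construction: with subjects as rows and raters as
    columns, ``icc = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)``
    and the confidence interval comes from the F distribution.

    Returns (icc, (lo, hi)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d score vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired scores")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ssr = k * np.sum((subj_means - grand) ** 2)
    ssc = n * np.sum((rater_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(ssr, 0.0):
        warnings.warn("zero between-subject variance; ICC set to 0")
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / denom

    # F-based interval (McGraw & Wong A,1 form)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, (1.0, 1.0)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lower), float(upper))


def pearson_with_ci(x: Sequence[float], y: Sequence[float], alpha: float = 0.05):
    """Pearson r with the Fisher-z normal-quantile confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs for a Fisher-z interval")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(len(x) - 3)
    q = stats.norm.ppf(1 - alpha / 2)
    return r, (math.tanh(z - q * se), math.tanh(z + q * se))


def error_metrics(deep: Sequence[float], bsid: Sequence[float]) -> dict:
    """MAE, RMSE and mean bias of ``deep - bsid`` with their spreads.

    ``bias_sd`` is the SD of the signed errors, ``mae_sd`` the SD of the
    absolute errors, and ``rmse_sd`` the SD of the squared errors (the
    spread of the quantity RMSE averages), each the sample SD (ddof=1).
    """
    deep = np.asarray(deep, dtype=float)
    bsid = np.asarray(bsid, dtype=float)
    if deep.size == 0 or deep.shape != bsid.shape:
        raise ValueError("deep and bsid must be nonempty and paired")
    e = deep - bsid
    ddof = 1 if len(e) > 1 else 0
    return {
        "mae": float(np.mean(np.abs(e))),
        "mae_sd": float(np.std(np.abs(e), ddof=ddof)),
        "rmse": float(np.sqrt(np.mean(e**2))),
        "rmse_sd": float(np.std(e**2, ddof=ddof)),
        "bias": float(np.mean(e)),
        "bias_sd": float(np.std(e, ddof=ddof)),
    }


def bland_altman_points(deep: Sequence[float], bsid: Sequence[float]):
    """Per-child (mean, difference) pairs and the 1.96-SD limits of agreement."""
    deep = np.asarray(deep, dtype=float)
    bsid = np.asarray(bsid, dtype=float)
    means = (deep + bsid) / 2.0
    diffs = deep - bsid
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return means, diffs, (bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class AgreementReport:
    """Agreement between predicted and benchmark scores on one dataset."""

    n: int
    pearson_r: float
    pearson_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    mae: float
    mae_sd: float
    rmse: float
    rmse_sd: float
    bias: float
    bias_sd: float
    loa: tuple[float, float]

    def __post_init__(self) -> None:
        assert -1.0 <= self.pearson_r <= 1.0
        assert self.mae >= 0 and self.mae <= self.rmse + 1e-12

    @classmethod
    def from_scores(cls, deep: Sequence[float], bsid: Sequence[float]) -> "AgreementReport":
        r, r_ci = pearson_with_ci(deep, bsid)
        icc, icc_ci = icc_2_1(deep, bsid)
        em = error_metrics(deep, bsid)
        _, _, loa = bland_altman_points(deep, bsid)
        return cls(
            n=len(np.asarray(deep)), pearson_r=r, pearson_ci=r_ci,
            icc=icc, icc_ci=icc_ci, loa=loa, **em,
        )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# discrimination


def percentile_cutoff(scores: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile of a score sample (the benchmark cutoff)."""
    s = np.sort(np.asarray(scores, dtype=float))
    rank = max(1, math.ceil(pct / 100.0 * len(s)))
    return float(s[rank - 1])


def choose_cutoff(deep: Sequence[float], positive: Sequence[bool]) -> float:
    """Score threshold maximizing sensitivity + specificity on training data.

    Predicted-positive means a score *below* the threshold (low predicted
    score flags a poor performer).  Candidates are midpoints between
    consecutive sorted unique scores plus the open ends; among ties the
    lowest threshold wins.
    """
    deep = np.asarray(deep, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or not positive.any():
        raise ValueError("both classes must be present to choose a cutoff")
    uniq = np.unique(deep)
    if len(uniq) == 1:
        warnings.warn("all scores identical; degenerate cutoff")
        return float(uniq[0])
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_j = candidates[0], -np.inf
    n_pos, n_neg = positive.sum(), (~positive).sum()
    for t in candidates:
        pred = deep < t
        sens = (pred & positive).sum() / n_pos
        spec = (~pred & ~positive).sum() / n_neg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def _auc_rank(deep: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney pair-counting AUC: P(score_pos < score_neg), ties 1/2."""
    ranks = stats.rankdata(deep)  # midranks handle ties
    n_pos = int(positive.sum())
    n_neg = len(deep) - n_pos
    # low scores flag positives, so count concordant (pos below neg) pairs
    u = ranks[~positive].sum() - n_neg * (n_neg + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ROCReport:
    """Discrimination of below-percentile benchmark performers."""

    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    accuracy: float
    n_positive: int
    n: int
    positive_class: str = "benchmark score below the training 25th percentile"

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.auc, self.accuracy):
            assert 0.0 <= v <= 1.0

    def to_dict(self) -> dict:
        return asdict(self)


def roc_analysis(
    deep: Sequence[float],
    bsid: Sequence[float],
    benchmark_cutoff: float,
    score_cutoff: float,
) -> ROCReport:
    """ROC metrics at a fixed score cutoff.

    ``benchmark_cutoff`` defines the positive class (benchmark strictly
    below it, normally its training-sample 25th percentile);
    ``score_cutoff`` is the decision threshold chosen on training data.
    """
    deep = np.asarray(deep, dtype=float)
    bsid = np.asarray(bsid, dtype=float)
    positive = bsid < benchmark_cutoff
    if positive.all() or not positive.any():
        raise ValueError("AUC undefined: one class only")
    pred = deep < score_cutoff
    sens = float((pred & positive).sum() / positive.sum())
    spec = float((~pred & ~positive).sum() / (~positive).sum())
    acc = float((pred == positive).mean())
    return ROCReport(
        cutoff=float(score_cutoff),
        sensitivity=sens,
        specificity=spec,
        auc=_auc_rank(deep, positive),
        accuracy=acc,
        n_positive=int(positive.sum()),
        n=len(deep),
    )


# ---------------------------------------------------------------------------
# bias analyses


@dataclass
class BiasReport:
    exposure_t: float
    exposure_p: float
    mean_error_exposed: float
    mean_error_unexposed: float
    fine_motor_r: float
    fine_motor_ci: tuple[float, float]
    fine_motor_r_squared: float

    def to_dict(self) -> dict:
        return asdict(self)


def exposure_bias_test(errors: Sequence[float], exposure: Sequence[bool]):
    """Equal-variance two-sample t-test of prediction errors by exposure.

    Returns (t, p, mean error exposed, mean error unexposed).
    """
    errors = np.asarray(errors, dtype=float)
    exposure = np.asarray(exposure, dtype=bool)
    a, b = errors[exposure], errors[~exposure]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each exposure group needs at least 2 children")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), float(a.mean()), float(b.mean())


def fine_motor_correlation(errors: Sequence[float], fine_motor: Sequence[float]):
    """Pearson r (with CI) of prediction errors vs fine-motor score, plus r^2."""
    r, ci = pearson_with_ci(errors, fine_motor)
    return r, ci, r * r


# ---------------------------------------------------------------------------
# floor / ceiling


@dataclass
class FloorCeilingReport:
    n_low: int
    n_high: int
    low_levels_played: list[int]
    high_levels_played: list[int]
    low_below_10_levels: int
    high_not_all_levels: int
    max_levels: int = 40

    def to_dict(self) -> dict:
        return asdict(self)


def floor_ceiling_analysis(
    bsid: Sequence[float],
    levels_played: Sequence[int],
    pct_low: float = 25.0,
    pct_high: float = 90.0,
    max_levels: int = 40,
) -> FloorCeilingReport:
    """Levels-played distributions of extreme benchmark scorers.

    Low group: benchmark strictly below its ``pct_low`` nearest-rank
    percentile; high group: strictly above the ``pct_high`` percentile.
    Headline counts: low scorers playing fewer than 10 levels (floor) and
    high scorers not attempting every level (ceiling).
    """
    bsid = np.asarray(bsid, dtype=float)
    lp = np.asarray(levels_played, dtype=int)
    lo_cut = percentile_cutoff(bsid, pct_low)
    hi_cut = percentile_cutoff(bsid, pct_high)
    low = bsid < lo_cut
    high = bsid > hi_cut
    for name, grp in (("low", low), ("high", high)):
        if not grp.any():
            warnings.warn(f"{name} percentile group empty; omitted")
    return FloorCeilingReport(
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        low_levels_played=sorted(int(v) for v in lp[low]),
        high_levels_played=sorted(int(v) for v in lp[high]),
        low_below_10_levels=int((lp[low] < 10).sum()),
        high_not_all_levels=int((lp[high] < max_levels).sum()),
        max_levels=max_levels,
    )


# ---------------------------------------------------------------------------
# orchestration over fitted results


@dataclass
class EvaluationBundle:
    """Train + test evaluation mirroring the study's performance table."""

    train_agreement: AgreementReport
    test_agreement: AgreementReport | None
    train_roc: ROCReport
    test_roc: ROCReport | None
    benchmark_cutoff: float
    score_cutoff: float
    bias: BiasReport | None
    floor_ceiling: FloorCeilingReport | None
    excluded_children: list[str]

    def to_dict(self) -> dict:
        return {
            "benchmark_cutoff": self.benchmark_cutoff,
            "score_cutoff": self.score_cutoff,
            "train_agreement": self.train_agreement.to_dict(),
            "test_agreement": self.test_agreement.to_dict() if self.test_agreement else None,
            "train_roc": self.train_roc.to_dict(),
            "test_roc": self.test_roc.to_dict() if self.test_roc else None,
            "bias": self.bias.to_dict() if self.bias else None,
            "floor_ceiling": self.floor_ceiling.to_dict() if self.floor_ceiling else None,
            "excluded_children": list(self.excluded_children),
        }

    def summary(self) -> str:
        def fmt(a: AgreementReport | None, r: ROCReport | None) -> list[str]:
            if a is None:
                return ["  (no test set)"]
            out = [
                f"  n = {a.n}",
                f"  Pearson r = {a.pearson_r:.3f} ({a.pearson_ci[0]:.3f}-{a.pearson_ci[1]:.3f})",
                f"  ICC(2,1)  = {a.icc:.3f} ({a.icc_ci[0]:.3f}-{a.icc_ci[1]:.3f})",
                f"  MAE = {a.mae:.2f} ({a.mae_sd:.2f}); RMSE = {a.rmse:.2f}; "
                f"bias = {a.bias:.2f} ({a.bias_sd:.2f})",
            ]
            if r is not None:
                out.append(
                    f"  ROC: AUC = {r.auc:.3f}, sens = {r.sensitivity:.3f}, "
                    f"spec = {r.specificity:.3f}, acc = {r.accuracy:.3f}"
                )
            return out

        lines = ["Evaluation", "==========", f"benchmark 25th-pct cutoff = {self.benchmark_cutoff:g}; "
                 f"score cutoff = {self.score_cutoff:.2f}", "", "training set:"]
        lines += fmt(self.train_agreement, self.train_roc)
        lines += ["", "test set:"]
        lines += fmt(self.test_agreement, self.test_roc)
        if self.bias is not None:
            b = self.bias
            lines += [
                "",
                f"exposure bias: t = {b.exposure_t:.3f}, p = {b.exposure_p:.3f} "
                f"(means {b.mean_error_exposed:.2f} vs {b.mean_error_unexposed:.2f})",
                f"fine-motor correlation of errors: r = {b.fine_motor_r:.3f}, "
                f"r^2 = {b.fine_motor_r_squared:.3f}",
            ]
        if self.floor_ceiling is not None:
            fc = self.floor_ceiling
            lines += [
                f"floor/ceiling: low n={fc.n_low} (<10 levels: {fc.low_below_10_levels}); "
                f"high n={fc.n_high} (not all {fc.max_levels} levels: {fc.high_not_all_levels})",
            ]
        if self.excluded_children:
            lines += ["", f"excluded from prediction: {', '.join(self.excluded_children)}"]
        return "\n".join(lines)


def evaluate_results(results, paperlike_percentile: bool = False) -> EvaluationBundle:
    """Evaluate fitted :class:`~playcog.model.DeepScoreResults`.

    The benchmark percentile defining the positive class is computed on
    the training sample and frozen for test evaluation unless
    ``paperlike_percentile``, which uses the combined sample.
    """
    model = results.model
    y = model.y
    tr_deep = results.train_scores
    tr_y = y.loc[tr_deep.index]

    if paperlike_percentile:
        pct_base = y.to_numpy()
    else:
        pct_base = tr_y.to_numpy()
    bench_cut = percentile_cutoff(pct_base, 25.0)

    positive_tr = tr_y.to_numpy() < bench_cut
    score_cut = choose_cutoff(tr_deep.to_numpy(), positive_tr)

    train_agreement = AgreementReport.from_scores(tr_deep.to_numpy(), tr_y.to_numpy())
    train_roc = roc_analysis(tr_deep.to_numpy(), tr_y.to_numpy(), bench_cut, score_cut)

    test_agreement = test_roc = None
    if len(results.test_scores):
        te_deep = results.test_scores
        te_y = y.loc[te_deep.index]
        test_agreement = AgreementReport.from_scores(te_deep.to_numpy(), te_y.to_numpy())
        try:
            test_roc = roc_analysis(te_deep.to_numpy(), te_y.to_numpy(), bench_cut, score_cut)
        except ValueError:
            test_roc = None

    bias = floor_ceiling = None
    cohort = getattr(model, "cohort", None)
    if cohort is not None:
        deep_all = pd.concat([tr_deep, results.test_scores])
        err = deep_all - y.loc[deep_all.index]
        meta = {c.child_id: c for c in cohort.children}
        exposure = np.array([meta[c].smartphone_exposure for c in err.index])
        fm_scores = np.array([meta[c].bsid_fine_motor for c in err.index])
        t, p, m1, m0 = exposure_bias_test(err.to_numpy(), exposure)
        r, ci, r2 = fine_motor_correlation(err.to_numpy(), fm_scores)
        bias = BiasReport(t, p, m1, m0, r, ci, r2)
        floor_ceiling = floor_ceiling_analysis(
            np.array([c.bsid_cognitive_raw for c in cohort.children]),
            cohort.levels_played(),
            max_levels=cohort.schema.total_levels,
        )

    return EvaluationBundle(
        train_agreement=train_agreement,
        test_agreement=test_agreement,
        train_roc=train_roc,
        test_roc=test_roc,
        benchmark_cutoff=bench_cut,
        score_cutoff=score_cut,
        bias=bias,
        floor_ceiling=floor_ceiling,
        excluded_children=list(results.excluded_test),
    )
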