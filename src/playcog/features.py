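"""Feature engineering: event logs -> the children x features matrix.

The feature taxonomy follows the gamified-assessment naming idiom:
``<game>_l<level>_<type>`` for per-level features, ``<game>_av_<type>`` /
``<game>_total_<type>`` for per-game aggregates, pair aggregates such as
``msjig_total_playtime``, and across-game sums such as
``sum_all_levels_played``.  Stages:

1. ``extract_raw_features`` - tablet-stage counts and timestamps per level;
2. ``derive_features``      - accuracies, rates, playtime, activity, and
   the per-game / pair / across-game aggregates;
3. ``impute_missing``       - missed levels: accuracy-family -> 0,
   completion time and latency -> the level timer, counts -> 0; aggregates
   recomputed from the filled per-level values;
4. ``skew_transform``       - |skew| > 1 columns get sqrt / square;
5. ``prune_correlated``     - greedy drop at |r| > 0.9;
6. ``build_interactions``   - pairwise products and ratios of a small
   subset, filtered by null fraction and correlation;
7. ``mas_o_menos``          - the sign-averaged standardized composite;
8. ``pca_features``         - leading principal components to a variance
   target;
9. final standardization.

All data-dependent fits (interaction subset, mas-o-menos weights, PCA
loadings, scaling) are computed on a designated set of training rows and
applied to all rows, so test rows never leak into fitted state.  Passing
``fit_ids=None`` reproduces whole-dataset fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .schema import GameSchema, LevelSession, default_schema
from .simulate import Cohort

__all__ = [
    "FeatureMeta",
    "FeatureMatrix",
    "FeatureConfig",
    "extract_raw_features",
    "derive_features",
    "impute_missing",
    "skew_transform",
    "prune_correlated",
    "build_interactions",
    "mas_o_menos",
    "pca_features",
    "assemble_feature_set",
]

RAW_TYPES = (
    "correctclicks", "incorrectclicks", "correctdrags", "incorrectdrags",
    "totaldrags", "backgroundevents", "latency", "first_event_ms",
    "last_event_ms", "completion_ms",
)
_RAW_COMMON = ("backgroundevents", "latency", "first_event_ms", "last_event_ms", "completion_ms")
_RAW_BY_GESTURE = {
    "tap": ("correctclicks", "incorrectclicks") + _RAW_COMMON,
    "drag": ("correctdrags", "incorrectdrags", "totaldrags") + _RAW_COMMON,
    "mixed": RAW_TYPES,
}
LEVEL_DERIVED_TYPES = (
    "accuracy_cbyi", "accuracy_cbyt", "correctrate", "playtime",
    "completion_time", "activity",
)
#: per-game mean aggregates over levels
AV_TYPES = ("accuracy_cbyi", "accuracy_cbyt", "correctrate", "latency", "activity", "playtime")
#: per-game sums over levels; key = level feature type, value = name in the total
TOTAL_TYPES = {
    "correctclicks": "correctclicks",
    "correctdrags": "correctdrags",
    "totaldrags": "totaldrags",
    "incorrectdrags": "incorrectdrag",
    "backgroundevents": "backgroundevents",
    "playtime": "playtime",
    "completion_time": "completion_time",
}
#: zero-filled on imputation
_IMPUTE_ZERO = {
    "correctclicks", "incorrectclicks", "correctdrags", "incorrectdrags",
    "totaldrags", "backgroundevents", "accuracy_cbyi", "accuracy_cbyt",
    "correctrate", "activity", "playtime",
}
#: filled with the level timer (in the feature's own unit)
_IMPUTE_TIMER_MS = {"latency", "first_event_ms", "last_event_ms", "completion_ms"}
_IMPUTE_TIMER_S = {"completion_time"}


@dataclass(frozen=True)
class FeatureMeta:
    """Provenance of one feature column."""

    name: str
    game_scope: str          # game code, pair code (e.g. "msjig"), or "across"
    level_scope: str | None  # "1".."6", "av", "total", or None
    feature_type: str
    stage: str               # tablet | derived | interaction | mom | pca
    transform: str = "none"  # none | sqrt | square


@dataclass
class FeatureMatrix:
    """Children x features with per-cell originally-missing mask."""

    values: pd.DataFrame                 # index: child_id, columns: feature names
    meta: dict[str, FeatureMeta]
    mask: pd.DataFrame                   # same shape; True = originally missing

    def __post_init__(self) -> None:
        assert list(self.values.columns) == list(self.meta)
        assert self.values.shape == self.mask.shape

    @property
    def child_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), dict(self.meta), self.mask.copy())

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(
            self.values[names].copy(),
            {n: self.meta[n] for n in names},
            self.mask[names].copy(),
        )

    def append_columns(
        self, values: pd.DataFrame, metas: Iterable[FeatureMeta],
        mask: pd.DataFrame | None = None,
    ) -> "FeatureMatrix":
        metas = list(metas)
        if mask is None:
            mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        new_meta = dict(self.meta)
        for m in metas:
            if m.name in new_meta:
                raise ValueError(f"duplicate feature name {m.name!r}")
            new_meta[m.name] = m
        return FeatureMatrix(
            pd.concat([self.values, values], axis=1),
            new_meta,
            pd.concat([self.mask, mask], axis=1),
        )

    def to_dir(self, out: str | Path) -> Path:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(out / "features.csv", index_label="child_id")
        self.mask.to_csv(out / "mask.csv", index_label="child_id")
        meta = {n: vars(m) for n, m in self.meta.items()}
        (out / "feature_meta.json").write_text(json.dumps(meta, indent=1))
        return out

    @classmethod
    def from_dir(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path / "features.csv", index_col="child_id")
        values.index = values.index.astype(str)
        mask = pd.read_csv(path / "mask.csv", index_col="child_id").astype(bool)
        mask.index = mask.index.astype(str)
        meta = {
            n: FeatureMeta(**d)
            for n, d in json.loads((path / "feature_meta.json").read_text()).items()
        }
        return cls(values, meta, mask)


# ---------------------------------------------------------------------------
# stage 1: tablet-stage extraction


def extract_raw_features(
    sessions: Sequence[LevelSession], schema: GameSchema | None = None
) -> FeatureMatrix:
    """Per-level counts and timestamps straight off the event stream.

    Unattempted levels are missing-flagged in every cell; an attempted
    level with no events keeps zero counts but missing timestamps.
    """
    schema = schema or default_schema()
    by_child: dict[str, dict[tuple[str, int], LevelSession]] = {}
    for s in sessions:
        s.validate(schema)
        by_child.setdefault(s.child_id, {})[(s.game_id, s.level)] = s

    columns: list[str] = []
    metas: dict[str, FeatureMeta] = {}
    for g in schema.games:
        for lvl in range(1, g.n_levels + 1):
            for ftype in _RAW_BY_GESTURE[g.gesture]:
                name = f"{g.game_id}_l{lvl}_{ftype}"
                columns.append(name)
                metas[name] = FeatureMeta(name, g.game_id, str(lvl), ftype, "tablet")

    child_ids = list(by_child)
    vals = np.full((len(child_ids), len(columns)), np.nan)
    for i, cid in enumerate(child_ids):
        row: dict[str, float] = {}
        for g in schema.games:
            for lvl in range(1, g.n_levels + 1):
                sess = by_child[cid].get((g.game_id, lvl))
                if sess is None or not sess.attempted:
                    continue
                p = f"{g.game_id}_l{lvl}_"
                cc = ci = dc = di = bg = 0
                first_correct = first = last = completion = np.nan
                n_corr = 0
                for ev in sess.events:
                    if np.isnan(first):
                        first = ev.t_ms
                    last = ev.t_ms
                    if ev.outcome == "background":
                        bg += 1
                    elif ev.outcome == "correct":
                        n_corr += 1
                        if np.isnan(first_correct):
                            first_correct = ev.t_ms
                        if n_corr == g.advance_threshold and np.isnan(completion):
                            completion = ev.t_ms
                        if ev.gesture == "tap":
                            cc += 1
                        else:
                            dc += 1
                    else:
                        if ev.gesture == "tap":
                            ci += 1
                        else:
                            di += 1
                row[p + "correctclicks"] = cc
                row[p + "incorrectclicks"] = ci
                row[p + "correctdrags"] = dc
                row[p + "incorrectdrags"] = di
                row[p + "totaldrags"] = dc + di + sum(
                    1 for ev in sess.events
                    if ev.gesture == "drag" and ev.outcome == "background"
                )
                row[p + "backgroundevents"] = bg
                row[p + "latency"] = first_correct
                row[p + "first_event_ms"] = first
                row[p + "last_event_ms"] = last
                row[p + "completion_ms"] = completion
        for j, name in enumerate(columns):
            if name in row:
                vals[i, j] = row[name]

    values = pd.DataFrame(vals, index=pd.Index(child_ids, name="child_id"), columns=columns)
    mask = values.isna()
    return FeatureMatrix(values, metas, mask)


# ---------------------------------------------------------------------------
# stage 2: derived features


def _attempted_indicator(fm: FeatureMatrix, schema: GameSchema) -> pd.DataFrame:
    """children x (game, level) attempted flags, from the count-cell mask."""
    cols = {}
    for g in schema.games:
        for lvl in range(1, g.n_levels + 1):
            cols[(g.game_id, lvl)] = ~fm.mask[f"{g.game_id}_l{lvl}_backgroundevents"]
    return pd.DataFrame(cols, index=fm.values.index)


def _level_derived(fm: FeatureMatrix, schema: GameSchema) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    attempted = _attempted_indicator(fm, schema)
    out, metas, masks = {}, {}, {}

    def col(name: str) -> pd.Series | float:
        # absent gesture-specific counts are structurally zero
        return fm.values[name] if name in fm.values.columns else 0.0

    for g in schema.games:
        timer_s = g.level_timer_s
        for lvl in range(1, g.n_levels + 1):
            p = f"{g.game_id}_l{lvl}_"
            att = attempted[(g.game_id, lvl)]
            correct = col(p + "correctclicks") + col(p + "correctdrags")
            incorrect = col(p + "incorrectclicks") + col(p + "incorrectdrags")
            bg = fm.values[p + "backgroundevents"]
            total = correct + incorrect + bg
            with np.errstate(invalid="ignore", divide="ignore"):
                acc_i = (correct / (correct + incorrect)).where(correct + incorrect > 0)
                acc_t = (correct / total).where(total > 0)
                playtime = (fm.values[p + "last_event_ms"] - fm.values[p + "first_event_ms"]) / 1000.0
                rate = (correct / playtime).where(playtime > 0)
                activity = (total / playtime).where(playtime > 0)
            completion = (fm.values[p + "completion_ms"] / 1000.0).where(
                ~fm.values[p + "completion_ms"].isna(), other=timer_s
            ).where(att)  # attempted & incomplete -> timer; unattempted -> NaN
            for ftype, series in (
                ("accuracy_cbyi", acc_i),
                ("accuracy_cbyt", acc_t),
                ("correctrate", rate),
                ("playtime", playtime),
                ("completion_time", completion),
                ("activity", activity),
            ):
                name = p + ftype
                out[name] = series
                masks[name] = series.isna()
                metas[name] = FeatureMeta(name, g.game_id, str(lvl), ftype, "derived")
    return pd.DataFrame(out), metas, pd.DataFrame(masks)


def _aggregates(
    level_values: pd.DataFrame, attempted: pd.DataFrame, schema: GameSchema,
    pair: tuple[str, str] = ("ms", "jig"),
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Per-game / pair / across-game aggregates computed from level columns.

    NaN-aware so it works both before imputation (provisional values) and
    after (exact).  An aggregate cell is missing-flagged only when every
    constituent level is missing.
    """
    out, metas, masks = {}, {}, {}

    def put(name, series, scope, lscope, ftype, missing=None):
        out[name] = series
        metas[name] = FeatureMeta(name, scope, lscope, ftype, "derived")
        masks[name] = series.isna() if missing is None else missing

    zero = pd.Series(0.0, index=level_values.index)

    def has(gid, ftype):
        return f"{gid}_l1_{ftype}" in level_values.columns

    def lv(gid, lvl, ftype):
        name = f"{gid}_l{lvl}_{ftype}"
        return level_values[name] if name in level_values.columns else zero

    game_corr, game_events, game_lp = {}, {}, {}
    for g in schema.games:
        gid = g.game_id
        levels = range(1, g.n_levels + 1)
        att = pd.concat([attempted[(gid, l)] for l in levels], axis=1)
        game_lp[gid] = att.sum(axis=1)
        put(f"{gid}_levels_played", game_lp[gid], gid, "total", "levels_played",
            missing=pd.Series(False, index=level_values.index))
        never = ~att.any(axis=1)
        for ftype in AV_TYPES:
            block = pd.concat([lv(gid, l, ftype) for l in levels], axis=1)
            put(f"{gid}_av_{ftype}", block.mean(axis=1), gid, "av", ftype,
                missing=block.isna().all(axis=1))
        for ltype, tname in TOTAL_TYPES.items():
            if not has(gid, ltype):
                continue
            block = pd.concat([lv(gid, l, ltype) for l in levels], axis=1)
            s = block.sum(axis=1, min_count=1)
            put(f"{gid}_total_{tname}", s, gid, "total", ltype,
                missing=block.isna().all(axis=1))
        corr = pd.concat(
            [lv(gid, l, "correctclicks") + lv(gid, l, "correctdrags") for l in levels], axis=1
        ).sum(axis=1, min_count=1)
        ev = pd.concat(
            [
                lv(gid, l, "correctclicks") + lv(gid, l, "correctdrags")
                + lv(gid, l, "incorrectclicks") + lv(gid, l, "incorrectdrags")
                + lv(gid, l, "backgroundevents")
                for l in levels
            ],
            axis=1,
        ).sum(axis=1, min_count=1)
        game_corr[gid], game_events[gid] = corr, ev

    # pair aggregates (default: the two drag-heavy puzzle games)
    pcode = "".join(pair)
    for tname in ("incorrectdrag", "playtime"):
        names = [f"{g}_total_{tname}" for g in pair]
        if not all(n in out for n in names):
            continue
        s = sum(out[n] for n in names)
        put(f"{pcode}_total_{tname}", s, pcode, "total", TOTAL_TYPES_INV.get(tname, tname),
            missing=pd.concat([masks[n] for n in names], axis=1).all(axis=1))

    # across-game sums
    no_mask = pd.Series(False, index=level_values.index)
    put("sum_all_levels_played", sum(game_lp.values()), "across", "total",
        "levels_played", missing=no_mask)
    comp = pd.concat(
        [lv(g.game_id, l, "completion_time") for g in schema.games for l in range(1, g.n_levels + 1)],
        axis=1,
    )
    put("sum_completion_time", comp.sum(axis=1, min_count=1), "across", "total",
        "completion_time", missing=comp.isna().all(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        acc_terms = []
        for gid in game_corr:
            r = game_corr[gid] / game_events[gid]
            acc_terms.append(r.where(game_events[gid] > 0, other=0.0).fillna(0.0))
    put("sum_total_accuracy_cbyt", sum(acc_terms), "across", "total",
        "accuracy_cbyt", missing=no_mask)
    pt = pd.concat(
        [lv(g.game_id, l, "playtime") for g in schema.games for l in range(1, g.n_levels + 1)],
        axis=1,
    )
    put("sum_total_playtime", pt.sum(axis=1, min_count=1), "across", "total", "playtime",
        missing=pt.isna().all(axis=1))
    put("sum_correct_events", sum(game_corr.values()), "across", "total", "correctclicks",
        missing=pd.concat(list(game_corr.values()), axis=1).isna().all(axis=1))
    put("sum_total_events", sum(game_events.values()), "across", "total", "backgroundevents",
        missing=pd.concat(list(game_events.values()), axis=1).isna().all(axis=1))
    return pd.DataFrame(out), metas, pd.DataFrame(masks)


TOTAL_TYPES_INV = {v: k for k, v in TOTAL_TYPES.items()}


def derive_features(raw: FeatureMatrix, schema: GameSchema | None = None) -> FeatureMatrix:
    """Append level-derived features and all aggregates to the raw matrix."""
    schema = schema or default_schema()
    lvl_vals, lvl_meta, lvl_mask = _level_derived(raw, schema)
    fm = raw.append_columns(lvl_vals, lvl_meta.values(), lvl_mask)
    attempted = _attempted_indicator(raw, schema)
    level_panel = pd.concat([raw.values, lvl_vals], axis=1)
    agg_vals, agg_meta, agg_mask = _aggregates(level_panel, attempted, schema)
    return fm.append_columns(agg_vals, agg_meta.values(), agg_mask)


# ---------------------------------------------------------------------------
# stage 3: imputation


def impute_missing(fm: FeatureMatrix, schema: GameSchema | None = None) -> FeatureMatrix:
    """Fill missed-level cells with their assigned values, then recompute
    every aggregate from the filled per-level columns.

    Accuracy-family and rate features get 0; completion time, latency and
    other timestamps get the level timer (the maximum time allowed);
    counts and playtime get 0.
    """
    schema = schema or default_schema()
    out = fm.copy()
    timers = {g.game_id: g.level_timer_s for g in schema.games}
    unruled = []
    for name, m in fm.meta.items():
        if m.level_scope in ("av", "total") or m.game_scope == "across":
            continue  # aggregates recomputed below
        col = out.values[name]
        if not col.isna().any():
            continue
        t = m.feature_type
        if t in _IMPUTE_ZERO:
            fill = 0.0
        elif t in _IMPUTE_TIMER_MS:
            fill = timers[m.game_scope] * 1000.0
        elif t in _IMPUTE_TIMER_S:
            fill = timers[m.game_scope]
        else:
            unruled.append(name)
            continue
        out.values[name] = col.fillna(fill)
    if unruled:
        raise ValueError(f"no imputation rule for feature(s): {unruled}")

    attempted = _attempted_indicator(fm, schema)
    level_cols = [n for n, m in out.meta.items()
                  if m.level_scope not in ("av", "total") and m.game_scope != "across"]
    agg_vals, _, _ = _aggregates(out.values[level_cols], attempted, schema)
    for name in agg_vals.columns:
        out.values[name] = agg_vals[name]
    assert not out.values.isna().any().any(), "imputation left undefined cells"
    return out


# ---------------------------------------------------------------------------
# stage 4: skew transform


def skew_transform(
    fm: FeatureMatrix, threshold: float = 1.0
) -> tuple[FeatureMatrix, dict[str, str]]:
    """Square-root right-skewed columns, square left-skewed ones.

    Skewness is the adjusted Fisher-Pearson sample coefficient.  Columns
    with skew > threshold are shifted so their minimum is >= 0 and
    square-rooted (renamed ``*_sqrt``); skew < -threshold are squared
    (``*_sq``).  Applied once, never iterated.
    """
    values = fm.values.copy()
    meta = dict(fm.meta)
    log: dict[str, str] = {}
    rename: dict[str, str] = {}
    for name in fm.names:
        col = values[name].to_numpy()
        if np.ptp(col) == 0:
            continue
        sk = stats.skew(col, bias=False)
        if sk > threshold:
            shifted = col - min(col.min(), 0.0)
            values[name] = np.sqrt(shifted)
            new = name + "_sqrt"
            rename[name] = new
            meta[new] = replace(meta.pop(name), name=new, transform="sqrt")
            log[name] = "sqrt"
        elif sk < -threshold:
            values[name] = np.square(col)
            new = name + "_sq"
            rename[name] = new
            meta[new] = replace(meta.pop(name), name=new, transform="square")
            log[name] = "square"
    values = values.rename(columns=rename)
    mask = fm.mask.rename(columns=rename)
    ordered = {n: meta[n] for n in values.columns}
    return FeatureMatrix(values, ordered, mask), log


# ---------------------------------------------------------------------------
# stage 5: correlation pruning


def prune_correlated(
    fm: FeatureMatrix, r_max: float = 0.9, fit_ids: Sequence[str] | None = None
) -> FeatureMatrix:
    """Greedy left-to-right drop of columns with |r| > r_max to a survivor.

    Deterministic: columns are scanned in matrix order and a column is
    dropped as soon as it correlates beyond ``r_max`` with any retained
    earlier column.  Zero-variance columns correlate with nothing and are
    retained with a warning.
    """
    rows = fm.values if fit_ids is None else fm.values.loc[list(fit_ids)]
    X = rows.to_numpy(dtype=float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} zero-variance column(s) retained during pruning",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        if const[j] or not keep or corr[j, keep].max() <= r_max:
            keep.append(j)
    return fm.select([fm.names[j] for j in keep])


# ---------------------------------------------------------------------------
# stage 6: interaction terms


def build_interactions(
    fm: FeatureMatrix,
    subset: Sequence[str],
    r_max: float = 0.9,
    max_null_frac: float = 0.15,
    fit_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Two-way products and both-direction ratios of ``subset`` columns.

    A candidate is kept only if it is defined (denominator nonzero) in more
    than ``1 - max_null_frac`` of the fit rows, and if its |r| with every
    already-retained column (existing features and earlier-accepted
    candidates) is <= r_max.  Surviving ratio columns have their remaining
    undefined cells filled with 0 and missing-flagged.
    """
    missing = [s for s in subset if s not in fm.meta]
    if missing:
        raise KeyError(f"interaction subset member(s) absent: {missing}")
    fit_rows = list(fit_ids) if fit_ids is not None else list(fm.values.index)

    def pair_scope(a: str, b: str) -> str:
        sa, sb = fm.meta[a].game_scope, fm.meta[b].game_scope
        return sa if sa == sb else "+".join(sorted({sa, sb}))

    candidates: list[tuple[str, pd.Series, FeatureMeta]] = []
    subset = list(subset)
    for i, a in enumerate(subset):
        for b in subset[i + 1:]:
            name = f"{a}_times_{b}"
            candidates.append((
                name, fm.values[a] * fm.values[b],
                FeatureMeta(name, pair_scope(a, b), None, "product", "interaction"),
            ))
    for a in subset:
        for b in subset:
            if a == b:
                continue
            denom = fm.values[b]
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = (fm.values[a] / denom).where(denom != 0)
            name = f"{a}_div_by_{b}"
            candidates.append((
                name, ratio,
                FeatureMeta(name, pair_scope(a, b), None, "ratio", "interaction"),
            ))

    retained = fm.values.loc[fit_rows].to_numpy(dtype=float)
    retained_sd = retained.std(axis=0)
    kept_vals, kept_metas, kept_mask = {}, [], {}
    for name, series, m in candidates:
        fit_col = series.loc[fit_rows]
        if fit_col.isna().mean() >= max_null_frac:
            continue
        filled = fit_col.fillna(0.0).to_numpy(dtype=float)
        sd = filled.std()
        if sd > 0:
            centered = filled - filled.mean()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (centered @ (retained - retained.mean(axis=0))) / (
                    len(filled) * sd * retained_sd
                )
            if np.nan_to_num(np.abs(r)).max() > r_max:
                continue
        kept_vals[name] = series.fillna(0.0)
        kept_mask[name] = series.isna()
        kept_metas.append(m)
        retained = np.column_stack([retained, filled])
        retained_sd = np.append(retained_sd, sd)
    if not kept_vals:
        return fm.copy()
    return fm.append_columns(pd.DataFrame(kept_vals), kept_metas, pd.DataFrame(kept_mask))


# ---------------------------------------------------------------------------
# stage 7: mas-o-menos


def mas_o_menos(
    fm_train: pd.DataFrame, y_train: Sequence[float], fm_apply: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Sign-averaged standardized composite.

    Each column is standardized with *training* mean/SD; its weight is the
    sign (+-1) of its training Pearson correlation with the outcome; the
    composite is the mean of weight x standardized value over the non-zero
    -weight columns.  Returns (scores for fm_apply rows, weights).
    """
    y = np.asarray(y_train, dtype=float)
    Xt = fm_train.to_numpy(dtype=float)
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all columns have zero variance")
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((Xt - mu).T @ yc) / (len(y) * sd * yc.std())
    w = np.where(usable, np.sign(np.nan_to_num(r)), 0.0)
    Za = (fm_apply.to_numpy(dtype=float) - mu) / np.where(usable, sd, 1.0)
    score = (Za[:, usable] * w[usable]).mean(axis=1)
    return (
        pd.Series(score, index=fm_apply.index, name="mom"),
        pd.Series(w, index=fm_train.columns, name="weight"),
    )


# ---------------------------------------------------------------------------
# stage 8: PCA augmentation


def pca_features(
    fm_train: pd.DataFrame,
    fm_apply: pd.DataFrame,
    var_target: float = 0.70,
) -> tuple[pd.DataFrame, PCA]:
    """Scores of the leading principal components reaching ``var_target``.

    Columns are standardized with training statistics; the decomposition
    is fit on training rows only and applied to all rows.  The component
    count is the smallest k with cumulative explained variance >= target,
    capped at the matrix rank.
    """
    Xt = fm_train.to_numpy(dtype=float)
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Zt = (Xt - mu) / sd_safe
    pca = PCA(svd_solver="full", random_state=0)
    pca.fit(Zt)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    k = min(k, len(cum))
    Za = (fm_apply.to_numpy(dtype=float) - mu) / sd_safe
    scores = pca.transform(Za)[:, :k]
    df = pd.DataFrame(
        scores, index=fm_apply.index, columns=[f"pc{i + 1}" for i in range(k)]
    )
    return df, pca


# ---------------------------------------------------------------------------
# stage 9: full assembly


@dataclass
class FeatureConfig:
    """Knobs of the featurization stages."""

    skew_threshold: float = 1.0
    r_max: float = 0.9
    n_interaction_subset: int = 20
    interaction_subset: list[str] | None = None
    max_null_frac: float = 0.15
    pca_var_target: float = 0.70
    scale_final: bool = True


def assemble_feature_set(
    cohort: Cohort,
    config: FeatureConfig | None = None,
    fit_ids: Sequence[str] | None = None,
) -> tuple[FeatureMatrix, dict]:
    """Run the full extract -> ... -> scale chain on a cohort.

    ``fit_ids`` designates the training children for every data-dependent
    fit (interaction subset, mas-o-menos, PCA, scaling); ``None`` fits on
    all rows (whole-dataset replication mode).  Returns the final matrix
    and a per-stage composition report.
    """
    cfg = config or FeatureConfig()
    schema = cohort.schema
    report: dict[str, int] = {}

    raw = extract_raw_features(cohort.sessions, schema)
    report["tablet"] = len(raw.names)
    fm = derive_features(raw, schema)
    report["derived"] = len(fm.names) - report["tablet"]
    fm = impute_missing(fm, schema)
    fm, transform_log = skew_transform(fm, cfg.skew_threshold)
    report["skew_transformed"] = len(transform_log)
    fm = prune_correlated(fm, cfg.r_max, fit_ids=fit_ids)
    report["pruned_set"] = len(fm.names)

    y = pd.Series(
        {c.child_id: float(c.bsid_cognitive_raw) for c in cohort.children}
    ).loc[fm.values.index]
    fit_rows = list(fit_ids) if fit_ids is not None else list(fm.values.index)

    subset = cfg.interaction_subset
    if subset is None:
        Xf = fm.values.loc[fit_rows]
        sd = Xf.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = Xf.apply(lambda col: col.corr(y.loc[fit_rows]))
        r = r.abs().fillna(0.0).where(sd > 0, 0.0)
        subset = list(r.sort_values(ascending=False).index[: cfg.n_interaction_subset])
    fm = build_interactions(fm, subset, cfg.r_max, cfg.max_null_frac, fit_ids=fit_ids)
    report["interactions"] = len(fm.names) - report["pruned_set"]

    base_cols = fm.values
    mom_scores, _ = mas_o_menos(base_cols.loc[fit_rows], y.loc[fit_rows], base_cols)
    fm = fm.append_columns(
        mom_scores.to_frame(),
        [FeatureMeta("mom", "across", None, "mom", "mom")],
    )
    report["mom"] = 1

    pcs, _ = pca_features(
        base_cols.loc[fit_rows], base_cols, var_target=cfg.pca_var_target
    )
    fm = fm.append_columns(
        pcs, [FeatureMeta(c, "across", None, "pca", "pca") for c in pcs.columns]
    )
    report["pca"] = pcs.shape[1]
    report["final"] = len(fm.names)

    if cfg.scale_final:
        Xf = fm.values.loc[fit_rows]
        mu, sd = Xf.mean(axis=0), Xf.std(axis=0)
        sd = sd.where(sd > 0, 1.0)
        fm = FeatureMatrix((fm.values - mu) / sd, fm.meta, fm.mask)
    report["interaction_subset"] = len(subset)
    return fm, report
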