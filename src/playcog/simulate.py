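"""Synthetic cohort generator.

No public telemetry exists for this kind of preschool gamified assessment,
so every downstream stage is exercised on simulated cohorts with a *known*
latent cognitive ability.  The generative model is deliberately the
simplest one that produces every statistical structure the analysis
assumes:

* latent ability ``theta ~ N(0, ability_sd^2)`` per child;
* per-gesture correctness ``P(correct) = logistic(a_g * theta - b_gl)``
  with a per-game discrimination ``a_g`` and a per-level difficulty
  ``b_gl`` increasing with level index (an item-response construction,
  which also yields ability-graded attrition because a level is unlocked
  only by completing the previous one);
* lognormal inter-gesture gaps whose mean shrinks with ability (faster,
  more fluent play for stronger children);
* whole-game engagement: a child is "engaged" with probability
  ``logistic(c + d * theta)``; engaged children attempt every game,
  non-engaged children only a short prefix.  The intercept ``c`` is
  calibrated numerically so the marginal probability of attempting all
  nine games matches the target (default 0.955);
* a linear-Gaussian outcome map producing an integer benchmark score on a
  31-point support, correlated ``rho`` with ability, plus an analogous
  fine-motor score and an exposure flag independent of gameplay (the null
  used by the downstream bias test).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .schema import (
    ChildRecord,
    GameSchema,
    GameplayEvent,
    LevelSession,
    default_schema,
    read_child_table,
    read_event_logs,
    write_child_table,
    write_event_logs,
)

__all__ = ["SimConfig", "Cohort", "simulate_cohort", "generate_gameplay", "generate_outcomes"]


@lru_cache(maxsize=64)
def _engagement_intercept(p_all: float, slope: float, sd: float) -> float:
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    theta = nodes * sd
    w = weights / weights.sum()

    def gap(c: float) -> float:
        return float(w @ expit(c + slope * theta)) - p_all

    return float(brentq(gap, -30.0, 30.0, xtol=1e-10))


@dataclass
class SimConfig:
    """All knobs of the generative model, with calibrated defaults."""

    n_children: int = 200
    seed: int = 0
    ability_sd: float = 1.0

    # item-response gameplay model
    game_discrimination: float = 1.2      # slope of correctness on theta
    difficulty_base: float = -1.0         # level-1 difficulty offset
    difficulty_step: float = 0.8          # added per extra level
    tempo_base_s: float = 1.5             # mean inter-gesture gap at theta=0
    tempo_theta: float = 0.25             # log-gap decrease per unit theta
    tempo_sigma: float = 0.5              # lognormal sigma of gaps
    background_rate: float = 0.08         # P(event is a stray background touch)
    max_events_per_level: int = 300

    # engagement (whole-game attrition)
    p_all_games: float = 0.955            # target P(attempt all nine games)
    engagement_slope: float = 1.0
    dropout_geom_p: float = 0.5           # prefix length for non-engaged children

    # outcome map
    outcome_mu: float = 70.0
    outcome_sigma: float = 5.5
    outcome_rho: float = 0.75
    support: tuple[int, int] = (57, 88)
    fine_motor_mu: float = 55.0
    fine_motor_sigma: float = 4.0
    fine_motor_rho: float = 0.5
    exposure_prob: float = 0.57

    def validate(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        for name in ("outcome_rho", "fine_motor_rho"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.exposure_prob <= 1.0):
            raise ValueError("exposure_prob outside [0, 1]")
        if not (0.0 < self.p_all_games < 1.0):
            raise ValueError("p_all_games outside (0, 1)")
        lo, hi = self.support
        if hi - lo != 31:
            raise ValueError(f"score support must span exactly 31 points, got {hi - lo}")
        if self.ability_sd <= 0 or self.tempo_base_s <= 0:
            raise ValueError("ability_sd and tempo_base_s must be positive")

    def engagement_intercept(self) -> float:
        """Intercept c with E_theta[logistic(c + d*theta)] = p_all_games.

        Solved by Gauss-Hermite quadrature + root bracketing; deterministic.
        """
        return _engagement_intercept(self.p_all_games, self.engagement_slope, self.ability_sd)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["support"] = list(self.support)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "support" in d:
            d["support"] = tuple(d["support"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Cohort:
    """A simulated (or loaded) study cohort: children + their telemetry."""

    children: list[ChildRecord]
    sessions: list[LevelSession]
    config: SimConfig | None = None
    schema: GameSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        ids = {c.child_id for c in self.children}
        for s in self.sessions:
            if s.child_id not in ids:
                raise ValueError(f"session child_id {s.child_id!r} not in child table")

    @property
    def child_ids(self) -> list[str]:
        return [c.child_id for c in self.children]

    def sessions_by_child(self) -> dict[str, list[LevelSession]]:
        out: dict[str, list[LevelSession]] = {c.child_id: [] for c in self.children}
        for s in self.sessions:
            out[s.child_id].append(s)
        return out

    def attempted_all_games(self) -> np.ndarray:
        """Boolean per child: at least one attempted level in every game."""
        per_child = self.sessions_by_child()
        flags = []
        for cid in self.child_ids:
            games = {s.game_id for s in per_child[cid] if s.attempted}
            flags.append(len(games) == len(self.schema.games))
        return np.asarray(flags)

    def levels_played(self) -> np.ndarray:
        """Number of attempted levels per child (max 40)."""
        per_child = self.sessions_by_child()
        return np.asarray(
            [sum(s.attempted for s in per_child[cid]) for cid in self.child_ids]
        )

    def to_dir(self, out: str | Path) -> Path:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        write_event_logs(self.sessions, out / "events.jsonl", self.schema)
        write_child_table(self.children, out / "children.csv")
        if self.config is not None:
            self.config.to_yaml(out / "sim_config.yaml")
        return out

    @classmethod
    def from_dir(cls, path: str | Path, schema: GameSchema | None = None) -> "Cohort":
        path = Path(path)
        schema = schema or default_schema()
        cfg = None
        if (path / "sim_config.yaml").exists():
            cfg = SimConfig.from_yaml(path / "sim_config.yaml")
        support = cfg.support if cfg is not None else (57, 88)
        return cls(
            children=read_child_table(path / "children.csv", support=support),
            sessions=read_event_logs(path / "events.jsonl", schema),
            config=cfg,
            schema=schema,
        )


# ---------------------------------------------------------------------------


def _simulate_level(
    theta: float,
    p_correct: float,
    gesture: str,
    timer_s: float,
    threshold: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GameplayEvent], bool]:
    """Events of one attempted level; returns (events, completed).

    The level ends at the gesture that reaches ``threshold`` correct
    responses, or when the timer expires.
    """
    mean_gap = cfg.tempo_base_s * math.exp(-cfg.tempo_theta * theta)
    n_max = cfg.max_events_per_level
    # lognormal with the requested mean: mu = log(mean) - sigma^2/2
    mu = math.log(mean_gap) - 0.5 * cfg.tempo_sigma**2
    gaps = rng.lognormal(mean=mu, sigma=cfg.tempo_sigma, size=n_max)
    times = np.cumsum(gaps)
    times = times[times <= timer_s]
    n = len(times)
    if n == 0:
        return [], False

    u = rng.random(n)
    is_bg = u < cfg.background_rate
    # reuse the residual uniform for correctness: monotone coupling in theta
    u2 = (u - cfg.background_rate) / (1.0 - cfg.background_rate)
    is_correct = (~is_bg) & (u2 < p_correct)

    if gesture == "mixed":
        gestures = np.where(rng.random(n) < 0.5, "tap", "drag")
    else:
        gestures = np.full(n, gesture)

    n_corr = np.cumsum(is_correct)
    completed = bool(n_corr[-1] >= threshold)
    if completed:
        stop = int(np.searchsorted(n_corr, threshold)) + 1  # include the winning gesture
    else:
        stop = n

    t_ms = np.minimum(np.round(times[:stop] * 1000).astype(int), int(timer_s * 1000))
    outcomes = np.where(is_bg[:stop], "background", np.where(is_correct[:stop], "correct", "incorrect"))
    events = [
        GameplayEvent(int(t), str(g), str(o))
        for t, g, o in zip(t_ms, gestures[:stop], outcomes)
    ]
    return events, completed


def generate_gameplay(
    theta: float,
    schema: GameSchema,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    child_id: str = "c0",
) -> list[LevelSession]:
    """Full telemetry for one child: one LevelSession per schema level.

    Unattempted levels are emitted with ``attempted=False`` and no events.
    Substreams are keyed per (child, game, level), so for a fixed input rng
    state the gesture-level random numbers are shared across values of
    ``theta`` — a common-random-numbers coupling under which attempted
    levels, completions and correct counts are non-decreasing in theta.
    """
    cfg = config or SimConfig()
    child_key = int(rng.integers(2**31))
    eng_rng = np.random.default_rng([child_key, 9999])

    c = cfg.engagement_intercept()
    engaged = eng_rng.random() < expit(c + cfg.engagement_slope * theta)
    if engaged:
        n_games = len(schema.games)
    else:
        n_games = min(int(eng_rng.geometric(cfg.dropout_geom_p)), len(schema.games) - 1)

    sessions: list[LevelSession] = []
    for gi, game in enumerate(schema.games):
        game_attempted = gi < n_games
        unlocked = True
        for level in range(1, game.n_levels + 1):
            attempted = game_attempted and unlocked
            if attempted:
                lvl_rng = np.random.default_rng([child_key, gi, level])
                p = float(
                    expit(
                        cfg.game_discrimination * theta
                        - (cfg.difficulty_base + cfg.difficulty_step * (level - 1))
                    )
                )
                events, completed = _simulate_level(
                    theta, p, game.gesture, game.level_timer_s,
                    game.advance_threshold, cfg, lvl_rng,
                )
                unlocked = completed
            else:
                events, completed = [], False
            sessions.append(
                LevelSession(
                    child_id=child_id,
                    game_id=game.game_id,
                    level=level,
                    attempted=attempted,
                    completed=completed,
                    events=events,
                )
            )
    return sessions


def generate_outcomes(
    theta: float, config: SimConfig, rng: np.random.Generator
) -> tuple[int, float, bool]:
    """Benchmark cognitive score, fine-motor score and exposure flag.

    ``bsid = round(clamp(mu + sigma*(rho*theta + sqrt(1-rho^2)*eps)))`` on
    the integer support; the fine-motor score is analogous (unrounded);
    exposure is Bernoulli and independent of everything else.
    """
    lo, hi = config.support
    rho = config.outcome_rho
    z = rho * theta + math.sqrt(1.0 - rho**2) * rng.standard_normal()
    bsid = int(round(min(max(config.outcome_mu + config.outcome_sigma * z, lo), hi)))

    rho_fm = config.fine_motor_rho
    z_fm = rho_fm * theta + math.sqrt(1.0 - rho_fm**2) * rng.standard_normal()
    fine_motor = float(config.fine_motor_mu + config.fine_motor_sigma * z_fm)

    exposure = bool(rng.random() < config.exposure_prob)
    return bsid, fine_motor, exposure


_PRESCHOOL = ("none", "private", "anganwadi")


def simulate_cohort(config: SimConfig | None = None, schema: GameSchema | None = None) -> Cohort:
    """Simulate a full cohort; deterministic given ``config.seed``."""
    cfg = config or SimConfig()
    cfg.validate()
    schema = schema or default_schema()
    rng = np.random.default_rng(cfg.seed)

    thetas = rng.normal(0.0, cfg.ability_sd, size=cfg.n_children)
    children: list[ChildRecord] = []
    sessions: list[LevelSession] = []
    width = len(str(cfg.n_children))
    for i, theta in enumerate(thetas):
        cid = f"c{i:0{width}d}"
        bsid, fine_motor, exposure = generate_outcomes(theta, cfg, rng)
        children.append(
            ChildRecord(
                child_id=cid,
                age_months=float(rng.uniform(34, 40)),
                sex=str(rng.choice(["f", "m"])),
                smartphone_exposure=exposure,
                preschool=str(rng.choice(_PRESCHOOL, p=[0.2, 0.35, 0.45])),
                bsid_cognitive_raw=bsid,
                bsid_fine_motor=round(fine_motor, 1),
                latent_ability=float(theta),
            )
        )
        sessions.extend(generate_gameplay(float(theta), schema, rng, cfg, child_id=cid))
    return Cohort(children=children, sessions=sessions, config=cfg, schema=schema)
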