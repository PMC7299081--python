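"""Game structure, telemetry containers and event-log / child-table I/O.

The assessment consists of nine touchscreen games, each with 2-6 difficulty
levels (40 levels in total).  Raw telemetry is a stream of gesture events
(taps and drags) with millisecond timestamps and an outcome of ``correct``,
``incorrect`` or ``background`` (a stray touch outside the active play
area).  A child plays levels sequentially within a game; a level is only
unlocked once the previous one was completed before its timer ran out.

Event logs are serialized as JSON-lines, one level session per line, and
the per-child benchmark table as CSV.  Both round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "GameDef",
    "GameSchema",
    "GameplayEvent",
    "LevelSession",
    "ChildRecord",
    "SchemaError",
    "ValidationError",
    "DEFAULT_SCORE_SUPPORT",
    "default_schema",
    "load_schema",
    "read_event_logs",
    "write_event_logs",
    "read_child_table",
    "write_child_table",
]

GESTURES = ("tap", "drag")
OUTCOMES = ("correct", "incorrect", "background")
GAME_GESTURES = ("tap", "drag", "mixed")

#: Inclusive integer support of the raw benchmark cognitive score.  The
#: default spans 31 points, matching the instrument's observed raw range.
DEFAULT_SCORE_SUPPORT = (57, 88)


class SchemaError(ValueError):
    """Raised when a game-schema definition violates its invariants."""


class ValidationError(ValueError):
    """Raised when telemetry records fail validation against the schema."""


@dataclass(frozen=True)
class GameDef:
    """Definition of one game: identity, level count, gesture and timing."""

    game_id: str
    name: str
    n_levels: int
    gesture: str = "tap"
    level_timer_s: float = 60.0
    advance_threshold: int = 5

    def __post_init__(self) -> None:
        if not (2 <= self.n_levels <= 6):
            raise SchemaError(
                f"game {self.game_id!r}: n_levels={self.n_levels} outside [2, 6]"
            )
        if self.level_timer_s <= 0:
            raise SchemaError(f"game {self.game_id!r}: level_timer_s must be > 0")
        if self.advance_threshold < 1:
            raise SchemaError(f"game {self.game_id!r}: advance_threshold must be >= 1")
        if self.gesture not in GAME_GESTURES:
            raise SchemaError(
                f"game {self.game_id!r}: gesture {self.gesture!r} not one of {GAME_GESTURES}"
            )


@dataclass(frozen=True)
class GameSchema:
    """The ordered collection of exactly nine games totalling 40 levels."""

    games: tuple[GameDef, ...]

    def __post_init__(self) -> None:
        if len(self.games) != 9:
            raise SchemaError(f"schema must contain exactly 9 games, got {len(self.games)}")
        ids = [g.game_id for g in self.games]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate game_id in schema")
        total = sum(g.n_levels for g in self.games)
        if total != 40:
            raise SchemaError(f"total level count must be 40, got {total}")

    @property
    def total_levels(self) -> int:
        return sum(g.n_levels for g in self.games)

    @property
    def game_ids(self) -> tuple[str, ...]:
        return tuple(g.game_id for g in self.games)

    def __getitem__(self, game_id: str) -> GameDef:
        for g in self.games:
            if g.game_id == game_id:
                return g
        raise KeyError(game_id)

    def __contains__(self, game_id: str) -> bool:
        return any(g.game_id == game_id for g in self.games)


@dataclass(frozen=True, slots=True)
class GameplayEvent:
    """One gesture: time since level start (ms), gesture kind, outcome."""

    t_ms: int
    gesture: str
    outcome: str


@dataclass
class LevelSession:
    """All events a child produced on one level of one game."""

    child_id: str
    game_id: str
    level: int
    attempted: bool
    completed: bool
    events: list[GameplayEvent] = field(default_factory=list)

    def validate(self, schema: GameSchema) -> None:
        if self.game_id not in schema:
            raise ValidationError(f"unknown game_id {self.game_id!r}")
        gdef = schema[self.game_id]
        if not (1 <= self.level <= gdef.n_levels):
            raise ValidationError(
                f"game {self.game_id!r}: level {self.level} outside 1..{gdef.n_levels}"
            )
        if not self.attempted and self.events:
            raise ValidationError(
                f"{self.child_id}/{self.game_id} L{self.level}: "
                "attempted=false but events present"
            )
        limit = gdef.level_timer_s * 1000
        prev = -1
        for ev in self.events:
            if ev.t_ms < 0 or ev.t_ms > limit:
                raise ValidationError(
                    f"{self.child_id}/{self.game_id} L{self.level}: "
                    f"t_ms={ev.t_ms} outside [0, {limit:.0f}]"
                )
            if ev.t_ms < prev:
                raise ValidationError(
                    f"{self.child_id}/{self.game_id} L{self.level}: timestamps not sorted"
                )
            if ev.gesture not in GESTURES:
                raise ValidationError(f"bad gesture {ev.gesture!r}")
            if ev.outcome not in OUTCOMES:
                raise ValidationError(f"bad outcome {ev.outcome!r}")
            prev = ev.t_ms


@dataclass
class ChildRecord:
    """Per-child covariates and benchmark scores.

    ``latent_ability`` is populated only for synthetic cohorts, where the
    generative ability is known; it is never consumed by the pipeline.
    """

    child_id: str
    age_months: float
    sex: str
    smartphone_exposure: bool
    preschool: str
    bsid_cognitive_raw: int
    bsid_fine_motor: float
    latent_ability: float | None = None

    def validate(self, support: tuple[int, int] = DEFAULT_SCORE_SUPPORT) -> None:
        lo, hi = support
        if not (lo <= self.bsid_cognitive_raw <= hi):
            raise ValidationError(
                f"{self.child_id}: bsid_cognitive_raw={self.bsid_cognitive_raw} "
                f"outside support [{lo}, {hi}]"
            )


_DEFAULT_GAMES = (
    # (id, name, n_levels, gesture, timer_s, advance_threshold)
    ("st", "single tap", 2, "tap", 60.0, 5),
    ("at", "alternate tap", 2, "tap", 60.0, 5),
    ("pb", "pop the balloons", 4, "tap", 60.0, 5),
    ("gg", "grouping game", 6, "drag", 60.0, 5),
    ("ho", "hidden objects", 6, "tap", 60.0, 5),
    ("oo", "odd one out", 6, "tap", 60.0, 5),
    ("ms", "matching shapes", 3, "drag", 60.0, 5),
    ("jig", "jigsaw", 5, "drag", 60.0, 5),
    ("lr", "left right", 6, "mixed", 60.0, 5),
)


def default_schema() -> GameSchema:
    """The built-in nine-game schema (level counts sum to 40)."""
    return GameSchema(tuple(GameDef(*row) for row in _DEFAULT_GAMES))


def load_schema(config: str | Path | None = None) -> GameSchema:
    """Load the game schema, optionally overridden by a YAML file.

    The YAML override is a mapping ``games: [{game_id, name, n_levels,
    gesture, level_timer_s, advance_threshold}, ...]``; omitted fields of a
    game present in the default schema fall back to the default values.
    """
    base = default_schema()
    if config is None:
        return base
    raw = yaml.safe_load(Path(config).read_text())
    if not isinstance(raw, dict) or "games" not in raw:
        raise SchemaError("schema override must be a mapping with a 'games' list")
    games = []
    for entry in raw["games"]:
        if not isinstance(entry, dict) or "game_id" not in entry:
            raise SchemaError(f"malformed game entry (missing game_id): {entry!r}")
        gid = entry["game_id"]
        defaults = {}
        if gid in base:
            g = base[gid]
            defaults = dict(
                name=g.name,
                n_levels=g.n_levels,
                gesture=g.gesture,
                level_timer_s=g.level_timer_s,
                advance_threshold=g.advance_threshold,
            )
        unknown = set(entry) - {
            "game_id", "name", "n_levels", "gesture", "level_timer_s", "advance_threshold",
        }
        if unknown:
            raise SchemaError(f"game {gid!r}: unknown field(s) {sorted(unknown)}")
        defaults.update({k: v for k, v in entry.items() if k != "game_id"})
        if "name" not in defaults:
            defaults["name"] = gid
        if "n_levels" not in defaults:
            raise SchemaError(f"game {gid!r}: n_levels required for a new game")
        games.append(GameDef(game_id=gid, **defaults))
    return GameSchema(tuple(games))


# ---------------------------------------------------------------------------
# event-log I/O (JSON-lines, one level session per line)

def _session_to_obj(s: LevelSession) -> dict:
    return {
        "child_id": s.child_id,
        "game_id": s.game_id,
        "level": s.level,
        "attempted": s.attempted,
        "completed": s.completed,
        "events": [
            {"t_ms": e.t_ms, "gesture": e.gesture, "outcome": e.outcome} for e in s.events
        ],
    }


def read_event_logs(path: str | Path, schema: GameSchema | None = None) -> list[LevelSession]:
    """Read and validate a JSON-lines event log.

    Returns sessions in file order (the writer groups them by child).  Every
    session is validated against ``schema`` (default schema when omitted);
    a malformed record raises :class:`ValidationError` naming the line.
    """
    schema = schema or default_schema()
    sessions: list[LevelSession] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                sess = LevelSession(
                    child_id=str(obj["child_id"]),
                    game_id=obj["game_id"],
                    level=int(obj["level"]),
                    attempted=bool(obj["attempted"]),
                    completed=bool(obj["completed"]),
                    events=[
                        GameplayEvent(int(e["t_ms"]), e["gesture"], e["outcome"])
                        for e in obj["events"]
                    ],
                )
                sess.validate(schema)
            except (KeyError, TypeError, json.JSONDecodeError) as exc:
                raise ValidationError(f"line {lineno}: malformed record ({exc})") from exc
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
            sessions.append(sess)
    return sessions


def write_event_logs(
    sessions: Iterable[LevelSession],
    path: str | Path,
    schema: GameSchema | None = None,
) -> Path:
    """Write sessions as JSON-lines; validates before writing (round-trip safe)."""
    schema = schema or default_schema()
    path = Path(path)
    lines = []
    for s in sessions:
        s.validate(schema)
        lines.append(json.dumps(_session_to_obj(s), separators=(",", ":")))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ---------------------------------------------------------------------------
# child-table I/O (CSV)

_CHILD_COLS = [
    "child_id", "age_months", "sex", "smartphone_exposure", "preschool",
    "bsid_cognitive_raw", "bsid_fine_motor", "latent_ability",
]


def write_child_table(children: Sequence[ChildRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(c) for c in children], columns=_CHILD_COLS)
    # repr gives the shortest exact decimal, so floats survive the round-trip
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def read_child_table(
    path: str | Path, support: tuple[int, int] = DEFAULT_SCORE_SUPPORT
) -> list[ChildRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CHILD_COLS[:-1]) - set(df.columns)
    if missing:
        raise ValidationError(f"child table missing column(s): {sorted(missing)}")
    children = []
    for row in df.itertuples(index=False):
        theta = getattr(row, "latent_ability", None)
        if theta is not None and pd.isna(theta):
            theta = None
        rec = ChildRecord(
            child_id=str(row.child_id),
            age_months=float(row.age_months),
            sex=str(row.sex),
            smartphone_exposure=bool(row.smartphone_exposure),
            preschool=str(row.preschool),
            bsid_cognitive_raw=int(row.bsid_cognitive_raw),
            bsid_fine_motor=float(row.bsid_fine_motor),
            latent_ability=None if theta is None else float(theta),
        )
        rec.validate(support)
        children.append(rec)
    return children
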