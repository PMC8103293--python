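"""Engines for the two cube games: roadrunner (speed) and maze (precision).

Roadrunner: a green dot walks the cube surface on its own, one grid step per
``delay`` seconds, where the delay is set by the level of difficulty
(LoD 0/1/2 -> 0.8/0.6/0.4 s).  Whenever the dot sits on the middle cell of a
face it turns left, turns right, or keeps straight, uniformly at random.
The player's job (keep the dot's face pointing up) does not influence the
dot, so the event log depends only on the schedule and the seed.

Maze: a white dot is steered by the player along a closed track of allowed
cells; stepping onto a blocked cell turns the dot red (``off_path_enter``)
and returning to the track turns it green again (``off_path_exit``).  The
track layout is fixed per LoD: level 0 crosses faces only at the middle of
an edge, level 1 also forces crossings at off-middle edge cells.

Both games run 60 s of warm-up (a replay of the easiest level, flagged by
time so feature extraction can drop it) followed by the scheduled segments:
six 30 s segments for roadrunner, four 60 s segments (LoDs 0,1,0,1) for the
maze.  Engines are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .cube import CubeTopology, Vec3, build_topology

ROADRUNNER = "roadrunner"
MAZE = "maze"

#: LoD -> dot dwell time in seconds (roadrunner)
ROADRUNNER_DELAYS: dict[int, float] = {0: 0.8, 1: 0.6, 2: 0.4}
ROADRUNNER_SEGMENT_S = 30.0
MAZE_SEGMENT_S = 60.0
MAZE_LODS = (0, 1, 0, 1)
WARMUP_S = 60.0
#: maze control cadence: at most one dot step per this many seconds
MAZE_STEP_S = 0.3

EVENT_KINDS = ("level_start", "dot_move", "off_path_enter", "off_path_exit", "session_end")


@dataclass(frozen=True)
class GameEvent:
    t: float
    kind: str
    cell: Optional[int] = None
    lod: Optional[int] = None


@dataclass(frozen=True)
class LevelSchedule:
    """Ordered difficulty segments of one game session, plus the warm-up."""

    game: str
    segments: tuple[tuple[int, float], ...]  # (lod, duration_s)
    warmup_duration: float = WARMUP_S
    delays: dict[int, float] = field(default_factory=lambda: dict(ROADRUNNER_DELAYS))

    def validate(self) -> None:
        if self.game == ROADRUNNER:
            lods = [lod for lod, _ in self.segments]
            if len(self.segments) != 6 or any(d != ROADRUNNER_SEGMENT_S for _, d in self.segments):
                raise ValueError("roadrunner schedule needs 6 segments of 30 s")
            if sorted(lods) != [0, 0, 1, 1, 2, 2] or lods[0] != 0:
                raise ValueError("roadrunner LoDs must each occur twice, starting at 0")
            if any(a == b for a, b in zip(lods, lods[1:])):
                raise ValueError("adjacent roadrunner segments must differ in LoD")
            if set(self.delays) != {0, 1, 2}:
                raise ValueError("roadrunner delays must map LoDs {0,1,2}")
        elif self.game == MAZE:
            if tuple(lod for lod, _ in self.segments) != MAZE_LODS or any(
                d != MAZE_SEGMENT_S for _, d in self.segments
            ):
                raise ValueError("maze schedule needs 4 segments of 60 s with LoDs (0,1,0,1)")
        else:
            raise ValueError(f"unknown game: {self.game}")

    @property
    def total_duration(self) -> float:
        return self.warmup_duration + sum(d for _, d in self.segments)

    def intervals(self) -> list[tuple[float, float, int, bool]]:
        """(start, end, lod, is_warmup) for warm-up plus every segment."""
        warm_lod = 0
        out = [(0.0, self.warmup_duration, warm_lod, True)]
        t = self.warmup_duration
        for lod, dur in self.segments:
            out.append((t, t + dur, lod, False))
            t += dur
        return out


def roadrunner_schedule(permutation: Sequence[int]) -> LevelSchedule:
    sched = LevelSchedule(
        game=ROADRUNNER,
        segments=tuple((int(lod), ROADRUNNER_SEGMENT_S) for lod in permutation),
    )
    sched.validate()
    return sched


def maze_schedule() -> LevelSchedule:
    return LevelSchedule(game=MAZE, segments=tuple((lod, MAZE_SEGMENT_S) for lod in MAZE_LODS))


@dataclass
class SessionLog:
    """Timestamped event record of one child playing one game."""

    child_id: str
    game: str
    schedule: LevelSchedule
    seed: int
    events: list[GameEvent]
    permutation_id: Optional[int] = None

    def dot_moves(self) -> list[GameEvent]:
        return [e for e in self.events if e.kind == "dot_move"]

    def cell_at_times(self, times: np.ndarray) -> np.ndarray:
        """Dot cell held piecewise-constant between dot_move events."""
        moves = self.dot_moves()
        if not moves:
            raise ValueError("session log contains no dot_move events")
        ts = np.array([e.t for e in moves])
        cells = np.array([e.cell for e in moves])
        idx = np.searchsorted(ts, np.asarray(times), side="right") - 1
        return cells[np.clip(idx, 0, len(cells) - 1)]

    def on_path_at_times(self, times: np.ndarray) -> np.ndarray:
        """On-track indicator reconstructed from alternating enter/exit events."""
        times = np.asarray(times, dtype=float)
        ok = np.ones(times.shape, dtype=float)
        state = 1
        t_change = [0.0]
        s_change = [1]
        for e in self.events:
            if e.kind == "off_path_enter":
                if state == 0:
                    raise ValueError("off_path_enter while already off path")
                state = 0
            elif e.kind == "off_path_exit":
                if state == 1:
                    raise ValueError("off_path_exit while on path")
                state = 1
            else:
                continue
            t_change.append(e.t)
            s_change.append(state)
        idx = np.searchsorted(np.array(t_change), times, side="right") - 1
        return np.array(s_change, dtype=float)[np.clip(idx, 0, len(s_change) - 1)]


# ---------------------------------------------------------------------------
# roadrunner
# ---------------------------------------------------------------------------

def enumerate_roadrunner_permutations() -> list[tuple[int, ...]]:
    """All admissible LoD orders: each of {0,1,2} twice, first 0, no repeats.

    The published game used exactly these 10 orders, assigned round-robin to
    players; canonical (lexicographic) sorting makes the list stable.
    """
    out = []
    for seq in itertools.product((0, 1, 2), repeat=6):
        if seq[0] != 0:
            continue
        if any(a == b for a, b in zip(seq, seq[1:])):
            continue
        if sorted(seq) != [0, 0, 1, 1, 2, 2]:
            continue
        out.append(seq)
    return sorted(out)


#: start pose of the dot: middle cell of the top face, heading along +x
_START_CELL = 4
_START_HEADING: Vec3 = (1, 0, 0)
_BOUNDARY_EPS = 1e-9


def run_roadrunner(
    schedule: LevelSchedule,
    seed: int,
    *,
    topology: Optional[CubeTopology] = None,
    child_id: str = "",
    permutation_id: Optional[int] = None,
) -> SessionLog:
    """Simulate the autonomous dot walk and return its event log.

    Moves happen at ``t = segment_start + k * delay`` for k >= 1; a move
    landing exactly on a segment boundary belongs to the next segment (so a
    30 s segment at delay 0.8 logs 37 moves).  The player's cube handling
    never alters the dot, so no controller argument exists here; orientation
    enters only through the sensor stream simulated elsewhere.
    """
    schedule.validate()
    if schedule.game != ROADRUNNER:
        raise ValueError("run_roadrunner requires a roadrunner schedule")
    topo = topology or build_topology()
    rng = np.random.default_rng(seed)

    cell, heading = _START_CELL, _START_HEADING
    events: list[GameEvent] = []
    for start, end, lod, _is_warm in schedule.intervals():
        events.append(GameEvent(start, "level_start", lod=lod))
        if start == 0.0:
            events.append(GameEvent(0.0, "dot_move", cell=cell, lod=lod))
        delay = schedule.delays[lod]
        k = 1
        while start + k * delay < end - _BOUNDARY_EPS:
            if topo.is_middle(cell):
                turn = rng.integers(3)  # 0 forward, 1 left, 2 right
                if turn == 1:
                    heading = topo.turn_left(cell, heading)
                elif turn == 2:
                    heading = topo.turn_right(cell, heading)
            cell, heading = topo.forward(cell, heading)
            events.append(GameEvent(start + k * delay, "dot_move", cell=cell, lod=lod))
            k += 1
    events.append(GameEvent(schedule.total_duration, "session_end"))
    return SessionLog(
        child_id=child_id,
        game=ROADRUNNER,
        schedule=schedule,
        seed=int(seed),
        events=events,
        permutation_id=permutation_id,
    )


# ---------------------------------------------------------------------------
# maze
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MazeLayout:
    lod: int
    path_cells: tuple[int, ...]
    blocked_cells: frozenset[int]

    def on_path(self, cell: int) -> bool:
        return cell not in self.blocked_cells


def _cells_from_grid(topo: CubeTopology, coords: Iterable[tuple[int, int, int]]) -> tuple[int, ...]:
    lookup = {tuple(g): i for i, g in enumerate(topo.grid.tolist())}
    return tuple(lookup[c] for c in coords)


def build_maze_layout(lod: int, *, topology: Optional[CubeTopology] = None) -> MazeLayout:
    """Fixed closed-loop track per difficulty level.

    Level 0 is the equatorial ring of middle-row cells: every edge crossing
    happens at the middle of a side.  Level 1 detours over the top face so
    that two crossings occur at off-middle edge cells, forcing the awkward
    "roll around the corner at the edge" manoeuvre.  Coordinates below are
    doubled grid positions on the side-3 cube (see :mod:`sensortoy.cube`).
    """
    if lod not in (0, 1):
        raise ValueError(f"maze LoD must be 0 or 1, got {lod}")
    topo = topology or build_topology()
    equator_tail = [
        (2, 3, 0), (0, 3, 0), (-2, 3, 0),      # +y face, middle ring
        (-3, 2, 0), (-3, 0, 0), (-3, -2, 0),   # -x face
        (-2, -3, 0), (0, -3, 0), (2, -3, 0),   # -y face
    ]
    if lod == 0:
        coords = [(3, -2, 0), (3, 0, 0), (3, 2, 0)] + equator_tail
    else:
        coords = [
            (3, -2, 0), (3, -2, 2),            # +x face, turning upward
            (2, -2, 3), (2, 0, 3), (2, 2, 3),  # across the +z face (off-middle crossings)
            (3, 2, 2), (3, 2, 0),              # back down the +x face
        ] + equator_tail
    path = _cells_from_grid(topo, coords)
    blocked = frozenset(range(topo.grid.shape[0])) - frozenset(path)
    return MazeLayout(lod=lod, path_cells=path, blocked_cells=blocked)


#: a maze controller: (t, current_cell, layout, rng) -> adjacent target cell or None
MazeController = Callable[[float, int, MazeLayout, np.random.Generator], Optional[int]]


def follow_path_controller() -> MazeController:
    """Perfect play: always step to the next cell along the track."""

    def ctrl(t: float, cell: int, layout: MazeLayout, rng: np.random.Generator) -> Optional[int]:
        if cell in layout.path_cells:
            i = layout.path_cells.index(cell)
            return layout.path_cells[(i + 1) % len(layout.path_cells)]
        return layout.path_cells[0]

    return ctrl


def run_maze(
    schedule: LevelSchedule,
    controller: MazeController,
    seed: int,
    *,
    topology: Optional[CubeTopology] = None,
    child_id: str = "",
) -> SessionLog:
    """Drive the maze with a controller queried once per 0.3 s control step.

    The dot is placed on the track start at every level boundary (the layout
    changes between LoDs); if the previous segment ended off-track an
    ``off_path_exit`` is logged at the boundary so enter/exit events always
    alternate.  A controller may return None to stand still, and may move
    onto blocked cells — that is exactly what the off-path events record.
    """
    schedule.validate()
    if schedule.game != MAZE:
        raise ValueError("run_maze requires a maze schedule")
    topo = topology or build_topology()
    rng = np.random.default_rng(seed)
    layouts = {lod: build_maze_layout(lod, topology=topo) for lod in (0, 1)}

    events: list[GameEvent] = []
    on_path = True
    for start, end, lod, _is_warm in schedule.intervals():
        layout = layouts[lod]
        if not on_path:
            events.append(GameEvent(start, "off_path_exit"))
            on_path = True
        events.append(GameEvent(start, "level_start", lod=lod))
        cell = layout.path_cells[0]
        events.append(GameEvent(start, "dot_move", cell=cell, lod=lod))
        k = 1
        while start + k * MAZE_STEP_S < end - _BOUNDARY_EPS:
            t = start + k * MAZE_STEP_S
            target = controller(t, cell, layout, rng)
            if target is not None:
                if not topo.are_adjacent(cell, target):
                    raise ValueError(f"controller step {cell}->{target} is not adjacent")
                cell = target
                events.append(GameEvent(t, "dot_move", cell=cell, lod=lod))
                now_on = layout.on_path(cell)
                if on_path and not now_on:
                    events.append(GameEvent(t, "off_path_enter", cell=cell, lod=lod))
                elif not on_path and now_on:
                    events.append(GameEvent(t, "off_path_exit", cell=cell, lod=lod))
                on_path = now_on
            k += 1
    events.append(GameEvent(schedule.total_duration, "session_end"))
    return SessionLog(
        child_id=child_id, game=MAZE, schedule=schedule, seed=int(seed), events=events
    )
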