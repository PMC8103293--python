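"""Game-engine checks: schedules, permutations, dot kinetics, maze events."""

import itertools

import numpy as np
import pytest

from sensortoy.games import (
    MAZE_STEP_S,
    ROADRUNNER_DELAYS,
    LevelSchedule,
    build_maze_layout,
    enumerate_roadrunner_permutations,
    follow_path_controller,
    maze_schedule,
    roadrunner_schedule,
    run_maze,
    run_roadrunner,
)

#: the ten level orders of the deployed roadrunner game
PUBLISHED_PERMUTATIONS = {
    (0, 1, 2, 0, 1, 2), (0, 1, 2, 0, 2, 1), (0, 1, 2, 1, 2, 0), (0, 1, 2, 1, 0, 2),
    (0, 2, 1, 0, 1, 2), (0, 2, 1, 0, 2, 1), (0, 2, 1, 2, 0, 1), (0, 2, 1, 2, 1, 0),
    (0, 1, 0, 2, 1, 2), (0, 2, 0, 1, 2, 1),
}


class TestPermutations:
    def test_matches_brute_force_oracle(self):
        oracle = {
            seq for seq in itertools.product((0, 1, 2), repeat=6)
            if seq[0] == 0
            and sorted(seq) == [0, 0, 1, 1, 2, 2]
            and all(a != b for a, b in zip(seq, seq[1:]))
        }
        assert set(enumerate_roadrunner_permutations()) == oracle

    def test_matches_published_set_of_ten(self):
        perms = enumerate_roadrunner_permutations()
        assert len(perms) == 10
        assert set(perms) == PUBLISHED_PERMUTATIONS
        assert all(p[0] == 0 for p in perms)
        assert perms == sorted(perms)


@pytest.fixture(scope="module")
def log(rr_schedule, topo):
    return run_roadrunner(rr_schedule, seed=42, topology=topo)


class TestRoadrunner:
    def test_move_counts_per_segment(self, log, rr_schedule):
        # floor(30 / delay), with boundary moves deferred to the next segment
        expected = {0: 37, 1: 49, 2: 74}
        for start, end, lod, warm in rr_schedule.intervals():
            if warm:
                continue
            n = sum(1 for e in log.dot_moves() if start <= e.t < end)
            assert n == expected[lod], (lod, n)

    def test_inter_move_intervals_equal_the_lod_delay(self, log, rr_schedule):
        for start, end, lod, warm in rr_schedule.intervals():
            ts = np.array(sorted(e.t for e in log.dot_moves() if start < e.t < end))
            if len(ts) > 1:
                assert np.allclose(np.diff(ts), rr_schedule.delays[lod], atol=1e-9)

    def test_all_dot_cells_valid_and_times_bounded(self, log, rr_schedule):
        for e in log.events:
            assert 0.0 <= e.t <= rr_schedule.total_duration
        assert all(0 <= e.cell <= 53 for e in log.dot_moves())

    def test_one_level_start_per_segment_plus_warmup(self, log):
        assert sum(1 for e in log.events if e.kind == "level_start") == 7

    def test_same_seed_reproduces_the_event_list(self, rr_schedule, topo):
        a = run_roadrunner(rr_schedule, seed=9, topology=topo)
        b = run_roadrunner(rr_schedule, seed=9, topology=topo)
        assert a.events == b.events

    def test_invalid_schedules_are_rejected(self):
        with pytest.raises(ValueError):
            roadrunner_schedule((0, 0, 1, 1, 2, 2))   # adjacent repeat
        with pytest.raises(ValueError):
            roadrunner_schedule((1, 0, 2, 0, 1, 2))   # does not start easy
        with pytest.raises(ValueError):
            roadrunner_schedule((0, 1, 2, 0, 1, 1))   # wrong multiset + repeat
        with pytest.raises(ValueError):
            run_roadrunner(maze_schedule(), seed=0)


class TestMazeLayouts:
    @pytest.mark.parametrize("lod", [0, 1])
    def test_path_is_a_single_closed_cycle(self, lod, topo):
        path = build_maze_layout(lod, topology=topo).path_cells
        assert len(set(path)) == len(path)
        for a, b in zip(path, path[1:] + path[:1]):
            assert topo.are_adjacent(a, b)

    def test_level0_crosses_faces_only_at_edge_middles(self, topo):
        path = build_maze_layout(0, topology=topo).path_cells
        for a, b in zip(path, path[1:] + path[:1]):
            if topo.face_of(a) != topo.face_of(b):
                ga, gb = topo.grid[a], topo.grid[b]
                shared = [i for i in range(3) if ga[i] == gb[i]]
                assert all(ga[i] == 0 for i in shared)  # crossing at the edge's middle

    def test_level1_has_an_off_middle_crossing(self, topo):
        path = build_maze_layout(1, topology=topo).path_cells
        off_middle = 0
        for a, b in zip(path, path[1:] + path[:1]):
            if topo.face_of(a) != topo.face_of(b):
                ga, gb = topo.grid[a], topo.grid[b]
                shared = [i for i in range(3) if ga[i] == gb[i]]
                if any(ga[i] != 0 for i in shared):
                    off_middle += 1
        assert off_middle >= 1

    def test_blocked_cells_complement_the_path(self, topo):
        lay = build_maze_layout(0, topology=topo)
        assert set(lay.path_cells) | set(lay.blocked_cells) == set(range(54))
        assert not set(lay.path_cells) & set(lay.blocked_cells)

    def test_bad_lod_rejected(self):
        with pytest.raises(ValueError):
            build_maze_layout(2)


class TestMazeRuns:
    def test_perfect_play_never_leaves_the_track(self, maze_sched, topo):
        log = run_maze(maze_sched, follow_path_controller(), seed=5, topology=topo)
        assert not [e for e in log.events if e.kind == "off_path_enter"]

    def test_leaving_once_within_a_level_logs_one_enter_no_exit(self, maze_sched, topo):
        def leaver(t, cell, layout, rng):
            if layout.on_path(cell):
                for nb in _neighbors(topo, cell):
                    if not layout.on_path(nb):
                        return nb
            return None  # off the track: freeze there

        log = run_maze(maze_sched, leaver, seed=5, topology=topo)
        warm = [e for e in log.events if e.t < 60.0 and e.kind.startswith("off_path")]
        assert [e.kind for e in warm] == ["off_path_enter"]

    def test_enter_and_exit_events_strictly_alternate(self, maze_sched, topo):
        def wanderer(t, cell, layout, rng):
            nbs = _neighbors(topo, cell)
            return nbs[rng.integers(len(nbs))]

        for seed in range(5):
            log = run_maze(maze_sched, wanderer, seed=seed, topology=topo)
            kinds = [e.kind for e in log.events if e.kind.startswith("off_path")]
            for a, b in zip(kinds, kinds[1:]):
                assert a != b
            if kinds:
                assert kinds[0] == "off_path_enter"

    def test_on_path_reconstruction_matches_event_bookkeeping(self, maze_sched, topo):
        def wanderer(t, cell, layout, rng):
            nbs = _neighbors(topo, cell)
            return nbs[rng.integers(len(nbs))]

        log = run_maze(maze_sched, wanderer, seed=3, topology=topo)
        times = np.arange(0, log.schedule.total_duration, MAZE_STEP_S / 3)
        ok = log.on_path_at_times(times)
        assert set(np.unique(ok)) <= {0.0, 1.0}
        assert 0.0 < ok.mean() < 1.0


def _neighbors(topo, cell):
    return topo.neighbors(cell)
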