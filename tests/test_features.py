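"""Feature-pipeline checks: filter, derivatives, game signals, aggregation."""

import numpy as np
import pytest
from scipy.signal import butter, freqz

from conftest import make_child
from sensortoy.features import (
    FeatureSelector,
    aggregate_features,
    alignment_signal,
    compute_signals,
    differentiate,
    extract_features,
    lowpass,
    magnitude,
    maze_ok_signal,
)
from sensortoy.games import (
    MAZE,
    ROADRUNNER,
    GameEvent,
    SessionLog,
    maze_schedule,
)
from sensortoy.players import (
    SensorStream,
    control_model,
    noise_free,
    simulate_session,
    true_alignment,
)

FS = 110.0


def two_pass_gain(freq_hz: float) -> float:
    """Analytic amplitude response of the forward-backward Butterworth."""
    b, a = butter(4, 4.0, btype="low", fs=FS)
    _, h = freqz(b, a, worN=[2 * np.pi * freq_hz / FS])
    return float(abs(h[0]) ** 2)


class TestLowpass:
    def test_unit_dc_gain(self):
        assert np.allclose(lowpass(np.full(2000, 3.7), FS), 3.7)

    @pytest.mark.parametrize("freq,rtol", [(1.0, 0.01), (10.0, 0.05)])
    def test_sinusoid_amplitude_matches_analytic_response(self, freq, rtol):
        t = np.arange(0, 60, 1 / FS)
        y = lowpass(np.sin(2 * np.pi * freq * t), FS)
        core = slice(len(y) // 4, 3 * len(y) // 4)  # avoid edge transients
        measured = np.sqrt(2) * np.std(y[core])
        assert measured == pytest.approx(two_pass_gain(freq), rel=rtol)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.ones(10), FS)
        with pytest.raises(ValueError):
            lowpass(np.ones(1000), rate=6.0)


class TestMagnitudeAndDerivative:
    def test_pythagorean_triple(self):
        xyz = np.tile([3.0, 4.0, 0.0], (5, 1))
        assert np.allclose(magnitude(xyz), 5.0)
        assert np.allclose(magnitude(np.zeros((5, 3))), 0.0)

    def test_static_gravity_only_stream_has_9_81_magnitude(self, rr_schedule, topo):
        child = make_child(0.9)
        stream, _ = simulate_session(child, ROADRUNNER, rr_schedule, 1, topology=topo,
                                     model=noise_free(control_model(0.9)))
        assert np.allclose(magnitude(stream.acc), 9.81, atol=1e-9)

    def test_ramp_and_constant(self):
        ramp = np.arange(200) * 0.25
        d = differentiate(ramp, FS)
        assert np.allclose(d[1:-1], 0.25 * FS)
        assert np.allclose(differentiate(np.full(50, 2.0), FS), 0.0)

    def test_sinusoid_derivative_matches_closed_form(self):
        f = 2.0
        t = np.arange(0, 10, 1 / FS)
        d = differentiate(np.sin(2 * np.pi * f * t), FS)
        expected = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        assert np.allclose(d[1:-1], expected[1:-1], atol=0.05 * 2 * np.pi * f)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            differentiate(np.ones(2), FS)


def _static_roadrunner_session(dot_cell: int, rr_schedule) -> tuple[SensorStream, SessionLog]:
    """Cube held still (top face up), dot parked on one cell: handmade."""
    n = int(round(rr_schedule.total_duration * FS))
    t = np.arange(n) / FS
    acc = np.tile([0.0, 0.0, -9.81], (n, 1))
    stream = SensorStream(t=t, acc=acc, gyro=np.zeros((n, 3)))
    events = [GameEvent(0.0, "level_start", lod=0),
              GameEvent(0.0, "dot_move", cell=dot_cell, lod=0),
              GameEvent(rr_schedule.total_duration, "session_end")]
    log = SessionLog(child_id="h", game=ROADRUNNER, schedule=rr_schedule,
                     seed=0, events=events)
    return stream, log


class TestAlignmentSignal:
    def test_perfect_hold_gives_cosine_one(self, rr_schedule, topo):
        stream, log = _static_roadrunner_session(4, rr_schedule)
        cs = alignment_signal(stream, log, topo)
        assert np.allclose(cs, 1.0, atol=1e-9)

    def test_dot_on_side_face_gives_cosine_zero(self, rr_schedule, topo):
        stream, log = _static_roadrunner_session(topo.middle_cell(1), rr_schedule)
        cs = alignment_signal(stream, log, topo)
        assert np.allclose(cs, 0.0, atol=1e-9)

    def test_recovers_simulator_ground_truth_without_noise(self, rr_schedule, topo):
        child = make_child(0.75)
        stream, log = simulate_session(child, ROADRUNNER, rr_schedule, 6, topology=topo,
                                       model=noise_free(control_model(0.75)))
        recovered = alignment_signal(stream, log, topo)
        assert np.abs(recovered - true_alignment(stream, log, topo)).max() < 0.01

    def test_missing_dot_moves_rejected(self, rr_schedule, topo):
        stream, log = _static_roadrunner_session(4, rr_schedule)
        bare = SessionLog(child_id="h", game=ROADRUNNER, schedule=rr_schedule, seed=0,
                          events=[e for e in log.events if e.kind != "dot_move"])
        with pytest.raises(ValueError):
            alignment_signal(stream, bare, topo)


def _maze_log(events_spec) -> SessionLog:
    sched = maze_schedule()
    events = [GameEvent(0.0, "level_start", lod=0),
              GameEvent(0.0, "dot_move", cell=13, lod=0)]
    events += [GameEvent(t, kind) for t, kind in events_spec]
    events.append(GameEvent(sched.total_duration, "session_end"))
    return SessionLog(child_id="h", game=MAZE, schedule=sched, seed=0, events=events)


class TestMazeOkSignal:
    def test_no_off_path_events_means_always_correct(self):
        ok = maze_ok_signal(_maze_log([]))
        assert ok.mean() == 1.0

    def test_half_time_off_path_means_half_correct(self):
        # off for the second half of every 60 s block
        spec = []
        for k in range(5):
            spec += [(60.0 * k + 30.0, "off_path_enter"), (60.0 * (k + 1), "off_path_exit")]
        ok = maze_ok_signal(_maze_log(spec))
        assert ok.mean() == pytest.approx(0.5, abs=0.001)

    def test_non_alternating_events_rejected(self):
        log = _maze_log([(10.0, "off_path_enter"), (20.0, "off_path_enter")])
        with pytest.raises(ValueError):
            maze_ok_signal(log)

    def test_error_prone_children_spend_less_time_on_path(self, maze_sched, topo):
        def mean_ok(error_rate):
            from dataclasses import replace

            model = replace(control_model(0.6), maze_error_rate=error_rate)
            child = make_child(0.6)
            vals = []
            for seed in range(20):
                _, log = simulate_session(child, MAZE, maze_sched, seed, topology=topo,
                                          model=model)
                vals.append(maze_ok_signal(log).mean())
            return np.mean(vals)

        assert mean_ok(0.3) < mean_ok(0.05)


@pytest.fixture(scope="module")
def rr_session(rr_schedule, topo):
    child = make_child(0.55, id="f1")
    stream, log = simulate_session(child, ROADRUNNER, rr_schedule, 8, topology=topo)
    return child, stream, log


class TestExtractFeatures:
    def test_both_family_has_8_sensor_2_game_2_general_columns(self, rr_session, topo):
        child, stream, log = rr_session
        row = extract_features(stream, log, FeatureSelector(frozenset({0, 1, 2}), "both"),
                               child, topo)
        feats = [k for k in row if k not in ("id", "label", "levels", "game")]
        assert len(feats) == 12

    @pytest.mark.parametrize("family,n", [("sensor", 10), ("game", 4), ("both", 12)])
    def test_family_column_counts(self, rr_session, topo, family, n):
        child, stream, log = rr_session
        row = extract_features(stream, log, FeatureSelector(frozenset({0}), family),
                               child, topo)
        feats = [k for k in row if k not in ("id", "label", "levels", "game")]
        assert len(feats) == n

    def test_single_level_pools_both_occurrences(self, rr_session, topo):
        child, stream, log = rr_session
        signals = compute_signals(stream, log, topo)
        from sensortoy.features import _selection_mask

        mask = _selection_mask(signals, log, frozenset({0}))
        assert mask.sum() == pytest.approx(60 * 110, abs=2)  # two 30 s segments

    def test_level_selections_partition_the_post_warmup_samples(self, rr_session, topo):
        child, stream, log = rr_session
        signals = compute_signals(stream, log, topo)
        from sensortoy.features import _selection_mask

        singles = [_selection_mask(signals, log, frozenset({l})) for l in (0, 1, 2)]
        union = _selection_mask(signals, log, frozenset({0, 1, 2}))
        assert np.array_equal(np.sum(singles, axis=0), union.astype(int))  # disjoint cover

    def test_constant_signal_has_zero_sd(self, rr_schedule, topo):
        child = make_child(0.9, id="f2")
        stream, log = simulate_session(child, ROADRUNNER, rr_schedule, 9, topology=topo,
                                       model=noise_free(control_model(1.0)))
        # overwrite with a strictly constant stream: SD features must vanish
        n = len(stream.t)
        const = SensorStream(t=stream.t, acc=np.tile([0, 0, -9.81], (n, 1)),
                             gyro=np.zeros((n, 3)))
        row = extract_features(const, log, FeatureSelector(frozenset({0, 1, 2}), "sensor"),
                               child, topo)
        assert row["a_sd"] == pytest.approx(0.0, abs=1e-9)
        assert row["jerk_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_selection_rejected(self, rr_session, topo):
        child, stream, log = rr_session
        signals = compute_signals(stream, log, topo)
        with pytest.raises(ValueError):
            aggregate_features(signals, log, FeatureSelector(frozenset({7}), "both"), child)

    def test_all_features_finite_across_a_small_cohort(self, rr_schedule, maze_sched, topo):
        from sensortoy.players import sample_cohort

        sel_rr = FeatureSelector(frozenset({0, 1, 2}), "both")
        sel_mz = FeatureSelector(frozenset({0, 1}), "both")
        for i, child in enumerate(sample_cohort(6, 0.5, 21)):
            for game, sched, sel in ((ROADRUNNER, rr_schedule, sel_rr),
                                     (MAZE, maze_sched, sel_mz)):
                stream, log = simulate_session(child, game, sched, 50 + i, topology=topo)
                row = extract_features(stream, log, sel, child, topo)
                vals = [v for k, v in row.items()
                        if k not in ("id", "gender", "label", "levels", "game")]
                assert np.all(np.isfinite(vals))
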