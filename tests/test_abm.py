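"""Spatial simulator: initialization, movement, foraging, observation, runs."""

import numpy as np
import pytest

import cbcontrol as c
from cbcontrol.core import EATER, NON_EATER, UNDECIDED


@pytest.mark.parametrize("kw", [
    {"N": 0}, {"N_l": -1}, {"q": 1.5}, {"pi": -0.1}, {"R_o": 0.0},
    {"T_max": 0}, {"record_stride": 0}, {"arena_half_width": -5},
])
def test_invalid_config_rejected(kw):
    with pytest.raises(c.ValidationError):
        c.AbmConfig(**kw)


class TestInitWorld:
    def test_deterministic_in_seed(self):
        cfg = c.AbmConfig(N_l=50)
        a, b = c.init_world(cfg, 42), c.init_world(cfg, 42)
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.vel, b.vel)
        assert np.array_equal(a.fly_pos, b.fly_pos)
        assert np.array_equal(a.fly_toxic, b.fly_toxic)

    def test_geometry_and_states(self):
        cfg = c.AbmConfig(N_l=200, q=0.3)
        w = c.init_world(cfg, 3)
        assert np.all(np.hypot(w.pos[:, 0], w.pos[:, 1]) <= cfg.init_disc_radius)
        assert np.all(np.abs(w.fly_pos) <= cfg.arena_half_width)
        assert np.all(w.state == UNDECIDED)
        assert np.all(w.fly_alive)
        speeds = np.hypot(w.vel[:, 0], w.vel[:, 1])
        np.testing.assert_allclose(speeds, cfg.movement.speed, rtol=1e-12)

    def test_toxicity_limits(self):
        assert c.init_world(c.AbmConfig(q=0.0, N_l=300), 5).fly_toxic.sum() == 0
        assert c.init_world(c.AbmConfig(q=1.0, N_l=300), 5).fly_toxic.sum() == 300

    def test_toxic_count_binomial(self):
        cfg = c.AbmConfig(N_l=500, q=0.3)
        counts = [c.init_world(cfg, s).fly_toxic.sum() for s in range(400)]
        se_mean = np.sqrt(500 * 0.3 * 0.7 / 400)
        assert abs(np.mean(counts) - 150) < 3.5 * se_mean


def _lone_bird_world(pos, vel, flies=((60.0, 60.0),), toxic=(False,), **cfg_kw):
    cfg = c.AbmConfig(N=1, N_l=len(flies), **cfg_kw)
    w = c.make_world(cfg, [pos], [vel], [UNDECIDED], list(flies), list(toxic))
    return cfg, w


class TestMovement:
    def test_far_bird_turns_toward_roost(self):
        mp = c.MovementParams(noise=0.0)
        cfg, w = _lone_bird_world((200.0, 0.0), (0.0, 1.0),
                                  movement=mp)
        w2 = c.movement_step(w, cfg)
        toward = -w2.pos[0] / np.linalg.norm(w2.pos[0])
        assert np.dot(w2.vel[0], toward) > np.dot(w.vel[0], toward)

    def test_repulsion_separation_not_decreasing(self):
        mp = c.MovementParams(noise=0.0)
        cfg = c.AbmConfig(N=2, N_l=1, movement=mp)
        # head-on birds inside the repulsion zone
        w = c.make_world(cfg, [(0.0, 0.0), (1.0, 0.0)],
                         [(1.0, 0.0), (-1.0, 0.0)],
                         [UNDECIDED, UNDECIDED], [(60.0, 60.0)], [False])
        d0 = np.linalg.norm(w.pos[1] - w.pos[0])
        w2 = c.movement_step(w, cfg)
        d1 = np.linalg.norm(w2.pos[1] - w2.pos[0])
        assert d1 >= d0

    def test_flock_remains_bounded(self):
        cfg = c.AbmConfig(N=50, N_l=1)
        w = c.init_world(cfg, 9)
        c.core._nb_seed(9)
        radii = []
        for _ in range(10_000):
            w = c.movement_step(w, cfg)
            radii.append(np.max(np.hypot(w.pos[:, 0], w.pos[:, 1])))
        # envelope: home radius plus a bounded homing-turn overshoot
        assert max(radii) < cfg.movement.home_radius + 40
        assert np.all(np.isfinite(w.pos))

    def test_speed_constant(self):
        cfg = c.AbmConfig(N=20, N_l=1)
        w = c.init_world(cfg, 1)
        for _ in range(50):
            w = c.movement_step(w, cfg)
        np.testing.assert_allclose(np.hypot(w.vel[:, 0], w.vel[:, 1]),
                                   cfg.movement.speed, rtol=1e-9)


class TestForagingAndObservation:
    def test_undecided_eats_good_fly_becomes_eater(self):
        cfg, w = _lone_bird_world((0.0, 0.0), (1.0, 0.0),
                                  flies=((0.5, 0.0),), toxic=(False,), pi=1.0)
        w2, events = c.foraging_step(w, cfg, rng=0)
        assert len(events) == 1
        ev = events[0]
        assert (ev.bird_id, ev.fly_id, ev.toxic) == (0, 0, False)
        assert not w2.fly_alive[0]
        w3 = c.observation_step(events, w2, cfg)
        assert w3.state[0] == EATER
        assert ev.observers == ()

    def test_eater_eats_toxic_becomes_non_eater(self):
        cfg, w = _lone_bird_world((0.0, 0.0), (1.0, 0.0),
                                  flies=((0.5, 0.0),), toxic=(True,), pi=0.0)
        w.state[0] = EATER
        w2, events = c.foraging_step(w, cfg, rng=0)
        assert len(events) == 1 and events[0].toxic
        w3 = c.observation_step(events, w2, cfg)
        assert w3.state[0] == NON_EATER

    def test_non_eater_never_tries(self):
        cfg, w = _lone_bird_world((0.0, 0.0), (1.0, 0.0),
                                  flies=((0.5, 0.0),), toxic=(False,), pi=1.0)
        w.state[0] = NON_EATER
        w2, events = c.foraging_step(w, cfg, rng=0)
        assert events == [] and w2.fly_alive[0]

    def test_undecided_declines_with_pi_zero(self):
        cfg, w = _lone_bird_world((0.0, 0.0), (1.0, 0.0),
                                  flies=((0.5, 0.0),), toxic=(False,), pi=0.0)
        _, events = c.foraging_step(w, cfg, rng=0)
        assert events == []

    def _observation_world(self, toxic_flags, fly_xy, states=None):
        n = 5
        cfg = c.AbmConfig(N=n, N_l=len(fly_xy), pi=1.0)
        # bird 0 at origin; birds 1-3 within R_o = 6; bird 4 far away
        pos = [(0.0, 0.0), (3.0, 0.0), (0.0, 4.0), (-5.0, 0.0), (10.0, 0.0)]
        vel = [(1.0, 0.0)] * n
        states = states or [UNDECIDED] * n
        return cfg, c.make_world(cfg, pos, vel, states, fly_xy, toxic_flags)

    def test_observers_within_radius_adopt_good_outcome(self):
        cfg, w = self._observation_world([False], [(0.2, 0.0)])
        w2, events = c.foraging_step(w, cfg, rng=1)
        assert len(events) == 1 and events[0].bird_id == 0
        w3 = c.observation_step(events, w2, cfg)
        assert list(w3.state) == [EATER, EATER, EATER, EATER, UNDECIDED]
        assert sorted(events[0].observers) == [1, 2, 3]

    def test_bad_event_reconverts_an_eater(self):
        cfg, w = self._observation_world(
            [True], [(0.2, 0.0)],
            states=[UNDECIDED, EATER, UNDECIDED, UNDECIDED, EATER])
        w2, events = c.foraging_step(w, cfg, rng=1)
        w3 = c.observation_step(events, w2, cfg)
        # observers 1-3 and the eater itself turn non-eater; bird 4 untouched
        assert list(w3.state) == [NON_EATER] * 4 + [EATER]

    def test_conflicting_observations_negative_dominates_any_order(self):
        n = 4
        cfg = c.AbmConfig(N=n, N_l=2, pi=1.0)
        pos = [(0.0, 0.0), (2.0, 0.0), (1.0, 0.0), (30.0, 0.0)]
        vel = [(1.0, 0.0)] * n
        # two flies eaten in the same step: one good (bird 0), one bad (bird 1)
        w = c.make_world(cfg, pos, vel, [EATER, EATER, UNDECIDED, UNDECIDED],
                         [(0.1, 0.0), (2.1, 0.0)], [False, True])
        w2, events = c.foraging_step(w, cfg, rng=3)
        assert len(events) == 2
        outcomes = []
        for perm in (events, events[::-1]):
            w3 = c.observation_step([
                c.EatEvent(e.t, e.bird_id, e.fly_id, e.toxic) for e in perm
            ], w2, cfg)
            assert w3.state[2] == NON_EATER  # saw both outcomes
            outcomes.append(list(w3.state))
        assert outcomes[0] == outcomes[1]

    def test_fly_consumed_at_most_once(self):
        # two adjacent committed eaters, one fly between them
        cfg = c.AbmConfig(N=2, N_l=1, pi=1.0)
        w = c.make_world(cfg, [(0.0, 0.0), (1.0, 0.0)],
                         [(1.0, 0.0), (1.0, 0.0)], [EATER, EATER],
                         [(0.5, 0.0)], [False])
        for s in range(20):
            _, events = c.foraging_step(w, cfg, rng=s)
            assert len(events) == 1


class TestRun:
    def test_determinism_bit_identical(self, small_cfg):
        cfg = small_cfg.replace(q=0.25)
        a, b = c.run(cfg, 77), c.run(cfg, 77)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.p_series, b.p_series)
        assert a.final_p == b.final_p and a.termination == b.termination
        la, lb = a.event_log, b.event_log
        for f in ("t", "bird_id", "fly_id", "toxic", "n_observers"):
            assert np.array_equal(getattr(la, f), getattr(lb, f))
        assert all(np.array_equal(x, y) for x, y in zip(la.observers, lb.observers))

    def test_q0_purity(self, small_cfg):
        for s in range(10):
            res = c.run(small_cfg.replace(q=0.0), s)
            assert res.event_log.toxic.sum() == 0
            assert res.termination != "all_non_eaters"
            # without bad experiences the eater count can never fall
            assert np.all(np.diff(res.p_series) >= 0)

    def test_q1_purity(self, small_cfg):
        for s in range(10):
            res = c.run(small_cfg.replace(q=1.0), s)
            assert np.all(res.event_log.toxic)
            assert np.all(res.p_series == 0.0) and res.final_p == 0.0

    def test_conservation_and_log_consistency(self, small_cfg):
        res = c.run(small_cfg.replace(q=0.3), 5)
        log = res.event_log
        # one record per consumed fly, never revived
        assert len(np.unique(log.fly_id)) == log.n_events
        world = c.init_world(small_cfg.replace(q=0.3), 5)
        assert log.n_events <= world.fly_pos.shape[0]
        # observers exclude the eater
        for i in range(log.n_events):
            assert log.bird_id[i] not in log.observers[i]
            assert log.n_observers[i] == len(log.observers[i])
        # state counts partition the flock; flies only ever die
        frame = res.as_frame()
        np.testing.assert_array_equal(
            frame.n_eaters + frame.n_non_eaters + frame.n_undecided,
            small_cfg.N)
        assert frame.n_lanternfly_alive.iloc[-1] == small_cfg.N_l - log.n_events
        assert np.all(np.diff(frame.n_lanternfly_alive) <= 0)
        np.testing.assert_allclose(frame.p, frame.n_eaters / small_cfg.N)

    def test_termination_all_consumed(self):
        cfg = c.AbmConfig(N=20, N_l=5, q=0.0, pi=1.0, T_max=100_000,
                          record_stride=100, arena_half_width=10.0,
                          init_disc_radius=9.0)
        res = c.run(cfg, 2)
        assert res.termination == "all_consumed"
        assert res.times[-1] < cfg.T_max

    def test_final_p_recorded_exactly_at_termination(self, small_cfg):
        res = c.run(small_cfg.replace(q=0.4), 11)
        assert res.p_series[-1] == res.final_p
        assert res.times[-1] <= small_cfg.T_max


def test_state_machine_soundness(small_cfg):
    """No bird re-enters 'undecided'; every change traces to that step's events."""
    cfg = small_cfg.replace(q=0.3, pi=0.05)
    w = c.init_world(cfg, 13)
    c.core._nb_seed(13)
    prev = w.state.copy()
    for _ in range(3000):
        w, events = c.advance(w, cfg)
        changed = np.nonzero(w.state != prev)[0]
        assert UNDECIDED not in w.state[changed]
        if len(changed) > 0:
            assert events, "state changed without any eating event"
            involved = {e.bird_id for e in events}
            for e in events:
                involved.update(e.observers)
            assert set(changed) <= involved
        prev = w.state.copy()


def test_mean_final_p_decreases_with_q(small_cfg):
    means = []
    for i, q in enumerate((0.0, 0.25, 0.5)):
        finals = [c.run(small_cfg.replace(q=q), 100 * i + k).final_p
                  for k in range(8)]
        means.append(np.mean(finals))
    assert means[0] > means[2]
    assert means[0] >= means[1] >= means[2] - 0.05
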