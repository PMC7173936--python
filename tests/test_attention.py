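import numpy as np
import pytest
from scipy.spatial import Voronoi

from attnflock.attention import (
    apply_direct_detection,
    apply_signaling,
    attention_matrix,
    evaluate_danger_response,
    select_k_nearest_objects,
    voronoi_restricted_kno,
)
from attnflock.dynamics import ModelParams, run_simulation
from attnflock.environment import EnvironmentSpec, generate_random_environment, torus_distance

from conftest import make_state


def brute_force_attention(focal, positions, env, k):
    """Exhaustive sort oracle: all torus distances, stable (distance, id) sort.

    Global ids: agents first (0..N-1), then danger sites.
    """
    pos = np.asarray(positions, float)
    n = len(pos)
    objs = []
    for j in range(n):
        if j != focal:
            objs.append((float(torus_distance(pos[j], pos[focal], env.box_size)), j))
    for l in range(env.n_ds):
        objs.append(
            (float(torus_distance(env.ds_positions[l], pos[focal], env.box_size)), n + l)
        )
    objs.sort()
    return objs[:k]


class TestSelectKNearestObjects:
    def test_slots_filled_by_closer_agents_block_ds(self):
        # three agents strictly closer than a DS that lies inside the
        # repulsion zone: the DS gets no slot, so the agent does not respond
        env = EnvironmentSpec(20.0, np.array([[5.8, 5.0]]))  # DS at d=0.8 < r
        state = make_state(
            [[5.0, 5.0], [5.2, 5.0], [5.0, 5.3], [4.6, 5.0], [9.0, 9.0]]
        )
        att = select_k_nearest_objects(0, state, env, k=3)
        assert [e.kind for e in att.entries] == ["agent"] * 3
        assert att.g == 0

    def test_ds_outside_zone_still_occupies_slot(self):
        env = EnvironmentSpec(20.0, np.array([[6.5, 5.0]]))  # d=1.5 > r=1
        state = make_state([[5.0, 5.0], [10.0, 10.0]])
        att = select_k_nearest_objects(0, state, env, k=1)
        assert att.entries[0].kind == "ds"
        assert att.g == 0  # perceived but ignored

    def test_saturation_returns_all_objects_sorted(self):
        env = generate_random_environment(3, 10.0, seed=0)
        rng = np.random.default_rng(1)
        state = make_state(rng.uniform(0, 10, (5, 2)))
        att = select_k_nearest_objects(2, state, env, k=50)
        assert len(att.entries) == 4 + 3  # every other agent + every DS
        dists = [e.distance for e in att.entries]
        assert dists == sorted(dists)

    def test_k_below_one_rejected(self):
        state = make_state([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            select_k_nearest_objects(0, state, EnvironmentSpec(10.0), k=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        env = EnvironmentSpec(12.0, rng.uniform(0, 12, (3, 2)))
        pos = rng.uniform(0, 12, (10, 2))
        state = make_state(pos)
        k = int(rng.integers(1, 9))
        focal = int(rng.integers(0, 10))
        expected = brute_force_attention(focal, pos, env, k)
        att = select_k_nearest_objects(focal, state, env, k)
        got = [
            (e.distance, e.object_id if e.kind == "agent" else 10 + e.object_id)
            for e in att.entries
        ]
        assert [g[1] for g in got] == [e[1] for e in expected]
        np.testing.assert_allclose([g[0] for g in got], [e[0] for e in expected])

    def test_prefix_monotonicity_in_k(self, rng):
        env = EnvironmentSpec(15.0, rng.uniform(0, 15, (4, 2)))
        state = make_state(rng.uniform(0, 15, (12, 2)))
        for k in range(1, 10):
            small = select_k_nearest_objects(3, state, env, k)
            large = select_k_nearest_objects(3, state, env, k + 1)
            assert large.entries[:k] == small.entries


class TestAttentionMatrix:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_agent_selection(self, seed):
        rng = np.random.default_rng(100 + seed)
        env = EnvironmentSpec(12.0, rng.uniform(0, 12, (4, 2)))
        pos = rng.uniform(0, 12, (15, 2))
        state = make_state(pos)
        k = int(rng.integers(1, 12))
        att = attention_matrix(pos, env, k)
        for i in range(15):
            ref = select_k_nearest_objects(i, state, env, k)
            expected_ids = [
                e.object_id if e.kind == "agent" else 15 + e.object_id
                for e in ref.entries
            ]
            assert att.idx[i].tolist()[: len(expected_ids)] == expected_ids
            assert att.g_flags(env.repulsion_radius)[i] == ref.g

    def test_empty_slots_padded(self):
        pos = np.array([[1.0, 1.0], [2.0, 2.0]])
        att = attention_matrix(pos, EnvironmentSpec(10.0), k=5)
        assert (att.idx[:, 1:] == -1).all()
        assert np.isinf(att.dist[:, 1:]).all()


class TestDangerResponse:
    def test_in_slot_ds_inside_zone_triggers(self):
        env = EnvironmentSpec(20.0, np.array([[5.5, 5.0]]))
        state = make_state([[5.0, 5.0]])
        att = select_k_nearest_objects(0, state, env, k=1)
        g, active = evaluate_danger_response(att)
        assert g == 1 and active == [0]

    def test_in_slot_ds_outside_zone_ignored(self):
        env = EnvironmentSpec(20.0, np.array([[6.5, 5.0]]))
        state = make_state([[5.0, 5.0]])
        att = select_k_nearest_objects(0, state, env, k=1)
        g, active = evaluate_danger_response(att)
        assert g == 0 and active == []

    def test_no_ds_entries_vacuous(self):
        env = EnvironmentSpec(20.0)
        state = make_state([[5.0, 5.0], [6.0, 5.0]])
        att = select_k_nearest_objects(0, state, env, k=1)
        assert evaluate_danger_response(att) == (0, [])


def voronoi_shell_oracle(positions, box_size):
    """Independent first-shell construction from Voronoi ridges (3x3 tiling)."""
    pos = np.asarray(positions, float)
    n = len(pos)
    shifts = np.array([[dx, dy] for dx in (-1, 0, 1) for dy in (-1, 0, 1)], float)
    tiled = (pos[None] + shifts[:, None] * box_size).reshape(-1, 2)
    vor = Voronoi(tiled)
    center0 = 4 * n
    adj = [set() for _ in range(n)]
    for p, q in vor.ridge_points:
        for a, b in ((p, q), (q, p)):
            if center0 <= a < center0 + n and (b % n) != a % n:
                adj[a % n].add(int(b % n))
    return adj


class TestVoronoiRestrictedKNO:
    def test_k1_returns_nearest_neighbor(self, rng):
        pos = rng.uniform(0, 10, (8, 2))
        env = EnvironmentSpec(10.0)
        state = make_state(pos)
        att = voronoi_restricted_kno(0, state, env, k=1)
        base = select_k_nearest_objects(0, state, env, k=1)
        # the nearest neighbor is always a Voronoi neighbor (Delaunay property)
        assert att.entries == base.entries

    def test_result_within_first_shell_when_large_enough(self, rng):
        pos = rng.uniform(0, 12, (20, 2))
        env = EnvironmentSpec(12.0)
        state = make_state(pos)
        shells = voronoi_shell_oracle(pos, 12.0)
        for focal in range(5):
            k = min(2, len(shells[focal]))
            att = voronoi_restricted_kno(focal, state, env, k=k)
            assert set(att.social_ids()) <= shells[focal]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_shell_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = 14
        pos = rng.uniform(0, 10, (n, 2))
        env = EnvironmentSpec(10.0, rng.uniform(0, 10, (3, 2)))
        state = make_state(pos)
        shells = voronoi_shell_oracle(pos, 10.0)
        k = int(rng.integers(1, 8))
        focal = int(rng.integers(0, n))
        candidates = set(shells[focal])
        if len(candidates) < k:
            candidates |= set().union(*(shells[j] for j in candidates)) - {focal}
        objs = [
            (float(torus_distance(pos[j], pos[focal], 10.0)), j) for j in candidates
        ] + [
            (float(torus_distance(env.ds_positions[l], pos[focal], 10.0)), n + l)
            for l in range(env.n_ds)
        ]
        objs.sort()
        expected = [j for _, j in objs[:k]]
        att = voronoi_restricted_kno(focal, state, env, k=k)
        got = [
            e.object_id if e.kind == "agent" else n + e.object_id for e in att.entries
        ]
        assert got == expected


class TestDirectDetection:
    def test_outside_all_zones_never_overrides(self, rng):
        env = EnvironmentSpec(20.0, np.array([[10.0, 10.0]]))
        override, containing = apply_direct_detection((3.0, 3.0), env, 1.0, rng)
        assert override is False and len(containing) == 0

    def test_certain_detection_inside_zone(self, rng):
        env = EnvironmentSpec(20.0, np.array([[10.0, 10.0], [10.5, 10.0]]))
        override, containing = apply_direct_detection((10.2, 10.0), env, 1.0, rng)
        assert override is True
        assert sorted(containing.tolist()) == [0, 1]

    def test_bernoulli_rate(self, rng):
        env = EnvironmentSpec(20.0, np.array([[10.0, 10.0]]))
        draws = [
            apply_direct_detection((10.1, 10.0), env, 0.5, rng)[0]
            for _ in range(10_000)
        ]
        assert abs(np.mean(draws) - 0.5) < 0.02

    def test_invalid_probability_rejected(self, rng):
        env = EnvironmentSpec(20.0, np.array([[10.0, 10.0]]))
        with pytest.raises(ValueError):
            apply_direct_detection((10.1, 10.0), env, 1.5, rng)

    def test_p_zero_recovers_base_model_trajectories(self):
        env = generate_random_environment(20, 10.0, seed=4)
        base = ModelParams(k=4, p_direct=0.0)
        res_a = run_simulation(env, base, n_agents=30, r_inf=0.1, total_time=20.0,
                               burn_in_time=0.0, record_every=10, seed=9)
        res_b = run_simulation(env, base, n_agents=30, r_inf=0.1, total_time=20.0,
                               burn_in_time=0.0, record_every=10, seed=9)
        np.testing.assert_array_equal(
            res_a.final_state.headings, res_b.final_state.headings
        )

    def test_p_one_every_agent_in_zone_responds(self):
        env = generate_random_environment(40, 10.0, seed=5)
        params = ModelParams(k=2, p_direct=1.0)
        res = run_simulation(env, params, n_agents=40, r_inf=0.0, total_time=10.0,
                             burn_in_time=0.0, record_every=5, seed=1)
        from scipy.spatial import cKDTree

        tree = cKDTree(env.ds_positions, boxsize=env.box_size)
        for frame in res.frames:
            inside = tree.query(frame.positions)[0] < env.repulsion_radius
            assert (frame.g >= inside).all()


class TestSignaling:
    def _setup(self, g_vec):
        # agent 0's slots: agents 1, 2, 3
        env = EnvironmentSpec(20.0)
        state = make_state([[5.0, 5.0], [5.4, 5.0], [5.0, 5.5], [4.4, 5.0], [9.0, 9.0]])
        atts = [select_k_nearest_objects(i, state, env, 3) for i in range(5)]
        return apply_signaling(atts, np.array(g_vec, dtype=bool))

    def test_single_signaler_monopolizes_attention(self):
        out = self._setup([0, 1, 0, 0, 0])
        assert out[0].social_ids() == [1]

    def test_no_signaler_leaves_set_unchanged(self):
        out = self._setup([0, 0, 0, 0, 0])
        assert out[0].social_ids() == [1, 2, 3]

    def test_two_signalers_both_kept(self):
        out = self._setup([0, 1, 0, 1, 0])
        assert sorted(out[0].social_ids()) == [1, 3]

    def test_responders_unchanged(self):
        out = self._setup([1, 1, 0, 0, 0])
        assert out[0].social_ids() == [1, 2, 3]
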