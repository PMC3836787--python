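import itertools

import networkx as nx
import numpy as np
import pytest

from txnet.layout import (
    LayoutParams,
    LayoutState,
    energy,
    forces,
    init_layout,
    run_layout,
    step,
)


def _dumbbell() -> nx.Graph:
    return nx.Graph([("a", "b")])


def test_init_layout_seed_determinism():
    g = nx.path_graph(5)
    p = LayoutParams(seed=7)
    a = init_layout(g, p)
    b = init_layout(g, p)
    assert np.array_equal(a.positions, b.positions)
    c = init_layout(g, LayoutParams(seed=8))
    assert not np.array_equal(a.positions, c.positions)
    assert a.positions.shape == (5, 2)
    assert np.all(a.velocities == 0)
    d3 = init_layout(g, LayoutParams(seed=7, dim=3))
    assert d3.positions.shape == (5, 3)


def test_init_layout_empty_graph_rejected():
    with pytest.raises(ValueError):
        init_layout(nx.Graph(), LayoutParams())


def test_two_disconnected_nodes_repel_equally():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.array([[0.0, 0.0], [2.0, 0.0]]),
        velocities=np.zeros((2, 2)),
    )
    p = LayoutParams(k_c=3.0)
    f = forces(g, st, p)
    np.testing.assert_allclose(f[0], [-3.0 / 4.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(f[1], [3.0 / 4.0, 0.0], atol=1e-12)


def test_connected_pair_balances_at_cube_root():
    p = LayoutParams(k_c=2.0, k_s=0.25)
    d_star = (p.k_c / p.k_s) ** (1 / 3)
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.array([[0.0, 0.0], [d_star, 0.0]]),
        velocities=np.zeros((2, 2)),
    )
    f = forces(_dumbbell(), st, p)
    np.testing.assert_allclose(f, 0.0, atol=1e-12)


def test_triangle_forces_respect_symmetry():
    g = nx.complete_graph(3)
    angles = np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
    pos = 0.7 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    st = LayoutState(nodes=[0, 1, 2], positions=pos, velocities=np.zeros((3, 2)))
    f = forces(g, st, LayoutParams())
    mags = np.linalg.norm(f, axis=1)
    assert mags.std() == pytest.approx(0.0, abs=1e-12)
    # each force is radial (parallel to the node's position vector)
    for i in range(3):
        cross = pos[i, 0] * f[i, 1] - pos[i, 1] * f[i, 0]
        assert cross == pytest.approx(0.0, abs=1e-12)


def test_nonfinite_positions_rejected():
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.array([[0.0, 0.0], [np.nan, 0.0]]),
        velocities=np.zeros((2, 2)),
    )
    with pytest.raises(ValueError):
        forces(_dumbbell(), st, LayoutParams())


def test_step_fixed_point_at_equilibrium():
    p = LayoutParams(k_c=1.0, k_s=1.0)
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.array([[0.0, 0.0], [1.0, 0.0]]),
        velocities=np.zeros((2, 2)),
    )
    after = step(_dumbbell(), st, p)
    np.testing.assert_allclose(after.positions, st.positions, atol=1e-12)
    np.testing.assert_allclose(after.velocities, 0.0, atol=1e-12)
    assert after.iteration == 1


def test_strong_damping_shrinks_speeds():
    g = nx.path_graph(4)
    p = LayoutParams(lam=20.0, seed=3)
    st = init_layout(g, p)
    # spread the nodes out so positional forces are weak and drag dominates
    st.positions = st.positions * 5.0
    st.velocities = np.random.default_rng(0).standard_normal(st.velocities.shape)
    speeds = [st.max_speed]
    for _ in range(10):
        st = step(g, st, p)
        speeds.append(st.max_speed)
    assert all(b < a for a, b in zip(speeds, speeds[1:]))


def test_integrator_consistency_under_dt_halving():
    g = nx.path_graph(3)
    st = init_layout(g, LayoutParams(seed=5))
    big = step(g, st, LayoutParams(seed=5, dt=0.02))
    small = step(g, st, LayoutParams(seed=5, dt=0.01))
    move_big = np.linalg.norm(big.positions - st.positions)
    move_small = np.linalg.norm(small.positions - st.positions)
    assert move_small < move_big


def test_dumbbell_relaxes_to_analytic_separation():
    p = LayoutParams(k_c=1.0, k_s=1.0, speed_tol=1e-5, seed=1)
    st = run_layout(_dumbbell(), p)
    assert st.converged
    d = np.linalg.norm(st.positions[0] - st.positions[1])
    assert d == pytest.approx(1.0, rel=0.01)


def test_triangle_relaxes_equilateral():
    st = run_layout(nx.complete_graph(3), LayoutParams(speed_tol=1e-5, seed=2))
    assert st.converged
    d = [
        np.linalg.norm(st.positions[i] - st.positions[j])
        for i, j in itertools.combinations(range(3), 2)
    ]
    assert max(d) / min(d) == pytest.approx(1.0, rel=0.02)


def test_disconnected_pair_drifts_apart():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    p = LayoutParams(seed=4, max_iter=500)
    st0 = init_layout(g, p)
    d0 = np.linalg.norm(st0.positions[0] - st0.positions[1])
    st = run_layout(g, p)
    d1 = np.linalg.norm(st.positions[0] - st.positions[1])
    assert d1 > d0


def test_energy_components():
    p = LayoutParams(k_c=1.0, k_s=1.0)
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.array([[0.0, 0.0], [1.0, 0.0]]),
        velocities=np.zeros((2, 2)),
    )
    kin, pot = energy(_dumbbell(), st, p)
    assert kin == 0.0
    assert pot == pytest.approx(1.0 + 0.5)  # k_c/d + k_s d^2/2 at d=1
    # the analytic equilibrium is a local minimum of the potential
    for eps in (-0.01, 0.01):
        st2 = LayoutState(
            nodes=["a", "b"],
            positions=np.array([[0.0, 0.0], [1.0 + eps, 0.0]]),
            velocities=np.zeros((2, 2)),
        )
        assert energy(_dumbbell(), st2, p)[1] > pot


def test_total_energy_dissipates_with_viscosity():
    g = nx.complete_graph(4)
    for seed in range(5):
        p = LayoutParams(lam=0.5, seed=seed)
        st = init_layout(g, p)
        total = []
        for _ in range(120):
            st = step(g, st, p)
            total.append(sum(energy(g, st, p)))
        settled = total[10:]
        assert all(b <= a + 1e-9 for a, b in zip(settled, settled[1:]))


def test_momentum_conserved_without_viscosity():
    g = nx.fast_gnp_random_graph(12, 0.3, seed=2)
    p = LayoutParams(lam=0.0, seed=6)
    st = init_layout(g, p)
    for _ in range(20):
        f = forces(g, st, p)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)
        st = step(g, st, p)


def test_run_layout_bit_reproducible():
    g = nx.fast_gnp_random_graph(15, 0.25, seed=8)
    p = LayoutParams(seed=11, max_iter=300)
    a = run_layout(g, p)
    b = run_layout(g, p)
    assert np.array_equal(a.positions, b.positions)
    assert a.iteration == b.iteration


def test_coincident_nodes_are_separated():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    st = LayoutState(
        nodes=["a", "b"],
        positions=np.zeros((2, 2)),
        velocities=np.zeros((2, 2)),
    )
    f = forces(g, st, LayoutParams(seed=0))
    assert np.isfinite(f).all()
    assert np.linalg.norm(f[0]) > 0  # jitter produced a finite repulsion
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)


def test_barnes_hut_converges_to_exact_forces():
    g = nx.fast_gnp_random_graph(40, 0.1, seed=9)
    p_exact = LayoutParams(seed=3)
    st = init_layout(g, p_exact)
    f_exact = forces(g, st, p_exact)
    for theta, tol in [(0.01, 1e-3), (0.3, 0.05)]:
        p_bh = LayoutParams(seed=3, repulsion="barnes_hut", theta=theta)
        f_bh = forces(g, st, p_bh)
        rel = np.linalg.norm(f_bh - f_exact) / np.linalg.norm(f_exact)
        assert rel < tol, theta


def test_clique_dumbbell_separates_cliques():
    g = nx.Graph()
    for i, j in itertools.combinations(range(8), 2):
        g.add_edge(f"a{i}", f"a{j}")
        g.add_edge(f"b{i}", f"b{j}")
    g.add_edge("a0", "b0")
    wins = 0
    for seed in range(10):
        st = run_layout(g, LayoutParams(seed=seed, max_iter=20_000))
        pos = st.position_of()
        intra = [
            np.linalg.norm(pos[f"{c}{i}"] - pos[f"{c}{j}"])
            for c in "ab"
            for i, j in itertools.combinations(range(8), 2)
        ]
        inter = [
            np.linalg.norm(pos[f"a{i}"] - pos[f"b{j}"])
            for i in range(8)
            for j in range(8)
        ]
        wins += np.mean(intra) < np.mean(inter)
    assert wins >= 9
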