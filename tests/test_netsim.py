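"""Unit tests for network assembly, coupling and integration."""

import numpy as np
import pytest

from hetsort.graphs import Graph, make_ws_graph
from hetsort.netsim import (
    NetworkModel,
    SimResult,
    coupling_currents,
    sample_initial_conditions,
    simulate_network,
)
from hetsort.node_models import FHNParams, SRKParams, simulate_single_cell
from hetsort.sortedness import Partition, random_partition


def _two_node_graph():
    return Graph(N=2, adjacency=[np.array([1]), np.array([0])])


def _small_model(kind="fhn", N=20, g_coup=0.05, G=0.3, seed=0):
    g = make_ws_graph(N, 4, 0.2, seed=seed)
    p = random_partition(N, 0.2, np.random.default_rng(seed))
    if kind == "fhn":
        pop = {1: FHNParams(I=2.0), 2: FHNParams(I=1.0)}
    else:
        pop = {1: SRKParams(gL=60.0), 2: SRKParams(gL=100.0)}
    return NetworkModel(kind=kind, graph=g, partition=p, pop_params=pop,
                        g_coup=g_coup, G=G)


class TestCoupling:
    def test_currents_sum_to_zero(self, ws1000):
        rng = np.random.default_rng(0)
        V = rng.normal(size=1000)
        I = coupling_currents(V, ws1000, 0.1)
        assert abs(I.sum()) < 1e-10

    def test_two_node_antisymmetry(self):
        I = coupling_currents(np.array([1.0, 0.0]), _two_node_graph(), 0.1)
        assert I == pytest.approx([0.1, -0.1])

    def test_uniform_voltage_gives_zero_current(self, ws1000):
        assert np.allclose(coupling_currents(np.full(1000, -1.3), ws1000, 0.2), 0.0)

    def test_shape_checked(self):
        with pytest.raises(ValueError):
            coupling_currents(np.zeros(3), _two_node_graph(), 0.1)


class TestModel:
    def test_global_drive_overrides_population_G(self):
        m = _small_model(G=0.4)
        assert all(p.G == 0.4 for p in m.pop_params.values())

    def test_missing_population_parameters(self):
        g = make_ws_graph(20, 4, 0.2, seed=0)
        p = random_partition(20, 0.2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="population"):
            NetworkModel(kind="fhn", graph=g, partition=p,
                         pop_params={1: FHNParams()})

    def test_negative_coupling_rejected(self):
        g = make_ws_graph(20, 4, 0.2, seed=0)
        p = random_partition(20, 0.2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            NetworkModel(kind="fhn", graph=g, partition=p,
                         pop_params={1: FHNParams(), 2: FHNParams()}, g_coup=-1.0)

    def test_node_param_expansion(self):
        m = _small_model()
        I = m.node_param("I")
        assert np.all(I[m.partition.labels == 1] == 2.0)
        assert np.all(I[m.partition.labels == 2] == 1.0)


class TestInitialConditions:
    def test_shapes_and_determinism(self):
        m = _small_model(kind="srk")
        Y1 = sample_initial_conditions(m, np.random.default_rng(42))
        Y2 = sample_initial_conditions(m, np.random.default_rng(42))
        assert Y1.shape == (3, 20)
        assert np.array_equal(Y1, Y2)

    def test_srk_calcium_nonnegative_n_zero(self):
        m = _small_model(kind="srk", N=40)
        Y = sample_initial_conditions(m, np.random.default_rng(1))
        assert np.all(Y[2] >= 0)
        assert np.all(Y[1] == 0)

    def test_fhn_recovery_zero(self):
        m = _small_model(kind="fhn")
        Y = sample_initial_conditions(m, np.random.default_rng(2))
        assert np.all(Y[1] == 0)


class TestSimulation:
    def test_fhn_network_runs_and_result_is_consistent(self):
        m = _small_model(g_coup=0.05, G=0.35)
        Y0 = sample_initial_conditions(m, np.random.default_rng(0))
        sim = simulate_network(m, Y0, t_span=(0.0, 200.0), n_out=800)
        assert sim.states.shape == (2, 20, 800)
        assert sim.feature_variable.shape == (20, 800)
        assert sim.transient_cutoff == pytest.approx(50.0)
        assert np.all(np.isfinite(sim.states))

    def test_bad_initial_condition_shape(self):
        m = _small_model()
        with pytest.raises(ValueError):
            simulate_network(m, np.zeros((2, 19)))

    def test_save_load_round_trip(self, tmp_path):
        m = _small_model()
        Y0 = sample_initial_conditions(m, np.random.default_rng(0))
        sim = simulate_network(m, Y0, t_span=(0.0, 50.0), n_out=100,
                               metadata={"note": "round-trip"})
        sim.save(tmp_path / "sim.npz")
        back = SimResult.load(tmp_path / "sim.npz")
        assert np.array_equal(sim.t, back.t)
        assert np.array_equal(sim.states, back.states)
        assert back.kind == "fhn"
        assert back.metadata["note"] == "round-trip"

    def test_sync_manifold_invariant(self):
        # identical nodes + identical ICs: coupling stays zero forever
        g = make_ws_graph(30, 4, 0.2, seed=1)
        labels = np.r_[np.ones(3, dtype=int), np.full(27, 2, dtype=int)]
        m = NetworkModel(
            kind="fhn", graph=g, partition=Partition(labels),
            pop_params={1: FHNParams(I=1.0), 2: FHNParams(I=1.0)},
            g_coup=0.5, G=0.5,
        )
        Y0 = np.tile(np.array([[-1.0], [0.0]]), (1, 30))
        sim = simulate_network(m, Y0, t_span=(0.0, 200.0), n_out=400)
        spread = np.ptp(sim.states[0], axis=0)  # across nodes at each time
        assert spread.max() < 1e-6

    def test_decoupled_network_matches_single_cells(self):
        # g_coup = 0: each node is an independent cell (tight tolerances
        # so solver-step phase drift does not mask the identity)
        m = _small_model(kind="fhn", N=6, g_coup=0.0, G=0.3, seed=2)
        Y0 = sample_initial_conditions(m, np.random.default_rng(3))
        sim = simulate_network(m, Y0, t_span=(0.0, 60.0), n_out=200,
                               rtol=1e-9, atol=1e-12)
        I = m.node_param("I")
        for i in range(6):
            p = FHNParams(I=float(I[i]), G=0.3)
            t, y = simulate_single_cell("fhn", p, t_span=(0.0, 60.0),
                                        y0=Y0[:, i], n_out=200,
                                        rtol=1e-9, atol=1e-12)
            assert np.max(np.abs(y[0] - sim.states[0, i])) < 1e-5

    def test_srk_network_short_run(self):
        m = _small_model(kind="srk", N=10, g_coup=5.0, G=0.4, seed=3)
        Y0 = sample_initial_conditions(m, np.random.default_rng(4))
        sim = simulate_network(m, Y0, t_span=(0.0, 5000.0), n_out=500)
        assert np.all(sim.states[2] >= 0)  # calcium stays physical
        assert np.all(np.isfinite(sim.states))
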