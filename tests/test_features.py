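"""Unit tests for peak counting, phase extraction and synchrony features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetsort.experiment import make_fixtures
from hetsort.features import (
    count_peaks,
    interburst_intervals,
    kuramoto_R,
    peak_times,
    phase_from_peaks,
    summarise,
)
from hetsort.graphs import make_ws_graph
from hetsort.netsim import NetworkModel, sample_initial_conditions, simulate_network
from hetsort.node_models import FHNParams
from hetsort.sortedness import random_partition


@pytest.fixture(scope="module")
def traces():
    return make_fixtures("traces")


class TestPeaks:
    def test_sinusoid_peak_count(self, traces):
        assert count_peaks(traces["t"], traces["sin7"]) == 7

    def test_constant_trace_has_no_peaks(self, traces):
        assert count_peaks(traces["t"], traces["constant"]) == 0

    def test_population_scale_suppresses_ripple(self, traces):
        # a tiny ripple is not an oscillation when judged against a
        # population-wide signal range
        ripple = 0.01 * traces["sin7"]
        assert count_peaks(traces["t"], ripple) == 7          # own scale
        assert count_peaks(traces["t"], ripple, scale=2.0) == 0  # network scale

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(offset=st.floats(-10, 10), gain=st.floats(0.1, 50))
    def test_affine_invariance(self, offset, gain):
        t = np.linspace(0, 1, 2001)
        x = np.sin(2 * np.pi * 7 * t)
        assert count_peaks(t, gain * x + offset, scale=2 * gain) == count_peaks(
            t, x, scale=2.0
        )

    def test_peak_times_near_analytic(self, traces):
        pk = peak_times(traces["t"], traces["sin7"])
        expected = (np.arange(7) + 0.25) / 7.0
        assert np.max(np.abs(pk - expected)) < 1e-3


class TestPhase:
    def test_phase_gains_two_pi_per_period(self, traces):
        pk = peak_times(traces["t"], traces["sin7"])
        phi = phase_from_peaks(traces["t"], pk)
        assert phi[0] == 0.0
        assert phi[-1] == pytest.approx(2 * np.pi * 6)
        assert np.all(np.diff(phi) >= 0)

    def test_requires_two_peaks(self, traces):
        with pytest.raises(ValueError):
            phase_from_peaks(traces["t"], np.array([0.5]))


class TestKuramoto:
    def test_identical_phases_give_unity(self):
        phi = np.tile(np.linspace(0, 20, 200), (5, 1))
        R_bar, R_t = kuramoto_R(phi)
        assert R_bar == pytest.approx(1.0)
        assert np.allclose(R_t, 1.0)

    def test_antiphase_pair_gives_zero(self):
        base = np.linspace(0, 20, 200)
        R_bar, _ = kuramoto_R(np.vstack([base, base + np.pi]))
        assert R_bar == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phase_fan_gives_zero(self):
        base = np.linspace(0, 20, 200)
        phis = np.vstack([base + 2 * np.pi * k / 8 for k in range(8)])
        R_bar, _ = kuramoto_R(phis)
        assert R_bar == pytest.approx(0.0, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        R_bar, R_t = kuramoto_R(rng.uniform(0, 2 * np.pi, size=(20, 100)))
        assert 0.0 <= R_bar <= 1.0
        assert np.all((R_t >= 0) & (R_t <= 1))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            kuramoto_R(np.zeros((1, 10)))


@pytest.fixture(scope="module")
def active_sim():
    g = make_ws_graph(30, 6, 0.2, seed=0)
    p = random_partition(30, 0.2, np.random.default_rng(0))
    m = NetworkModel(
        kind="fhn", graph=g, partition=p,
        pop_params={1: FHNParams(I=2.0), 2: FHNParams(I=1.0)},
        g_coup=0.3, G=0.5,
    )
    Y0 = sample_initial_conditions(m, np.random.default_rng(1))
    return simulate_network(m, Y0, t_span=(0.0, 400.0), n_out=1600), p


class TestSummarise:
    def test_active_network_summary(self, active_sim):
        sim, p = active_sim
        f = summarise(sim, p)
        assert f.P_bar > 0
        assert f.synchrony_defined
        assert 0.0 <= f.R_bar <= 1.0
        assert f.n_oscillating == 30  # strong coupling, supra-threshold drive
        assert set(f.P_bar_k) == {1, 2}
        d = f.as_dict()
        assert {"P_bar", "R_bar", "P_bar_1", "R_bar_2"} <= set(d)

    def test_quiescent_network_summary(self):
        g = make_ws_graph(20, 4, 0.2, seed=1)
        p = random_partition(20, 0.2, np.random.default_rng(2))
        m = NetworkModel(
            kind="fhn", graph=g, partition=p,
            pop_params={1: FHNParams(I=1.0), 2: FHNParams(I=1.0)},
            g_coup=0.1, G=0.0,
        )
        Y0 = sample_initial_conditions(m, np.random.default_rng(3))
        sim = simulate_network(m, Y0, t_span=(0.0, 300.0), n_out=600)
        f = summarise(sim, p)
        assert f.P_bar == pytest.approx(0.0, abs=0.1)
        assert not f.synchrony_defined
        assert f.R_bar == 0.0


class TestInterburst:
    def test_square_wave_gaps(self):
        # 100 ms bursts separated by 400 ms of silence
        t = np.arange(0.0, 5000.0, 1.0)
        V = np.where((t % 500.0) < 100.0, 0.0, -60.0)
        ibi = interburst_intervals(t, V)
        assert len(ibi) >= 8
        assert np.allclose(ibi, 400.0, atol=2.0)

    def test_intra_burst_gaps_discarded(self):
        # bursts of 3 spikes (20 ms apart) every 500 ms: the short
        # intra-burst gaps must not survive
        t = np.arange(0.0, 5000.0, 0.5)
        V = np.full_like(t, -60.0)
        for start in np.arange(0.0, 4500.0, 500.0):
            for k in range(3):
                V[(t >= start + 20 * k) & (t < start + 20 * k + 5)] = 0.0
        ibi = interburst_intervals(t, V)
        assert np.all(ibi > 300.0)

    def test_flat_trace_gives_empty(self):
        t = np.linspace(0, 100, 500)
        assert len(interburst_intervals(t, np.full_like(t, -60.0))) == 0
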