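"""Unit and property tests for the sortedness metric and the sorter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetsort.graphs import make_bc_lattice, make_ws_graph
from hetsort.sortedness import (
    Partition,
    build_selection_pdf,
    modified_node_sortedness,
    network_sortedness,
    node_sortedness,
    random_partition,
    sort_network,
    sortedness_delta,
)


class TestPartition:
    def test_labels_must_be_one_based_contiguous(self):
        with pytest.raises(ValueError):
            Partition(np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            Partition(np.array([1, 3, 1, 3]))  # population 2 empty

    def test_random_partition_counts(self):
        p = random_partition(1000, 0.1, np.random.default_rng(0))
        assert np.sum(p.labels == 1) == 100
        assert p.K == 2

    def test_random_partition_rounds(self):
        p = random_partition(25, 0.1, np.random.default_rng(0))
        assert np.sum(p.labels == 1) == 2  # round(2.5) banker's -> 2


class TestMetric:
    def test_alternating_ring_is_perfectly_unsorted(self, ring6):
        A = network_sortedness(ring6["graph"], ring6["partition"])
        assert A == pytest.approx(-1.0, abs=1e-15)

    def test_node_sortedness_hand_computed(self, ring6):
        # every node's two neighbours are the other population
        for i in range(6):
            assert node_sortedness(ring6["graph"], ring6["partition"], i) == 0.0

    def test_blocked_ring_is_maximally_sorted(self):
        # two contiguous arcs on a ring: only 2 of 12 edge endpoints cross
        adjacency = [np.sort(np.array([(i - 1) % 12, (i + 1) % 12])) for i in range(12)]
        from hetsort.graphs import Graph

        g = Graph(N=12, adjacency=adjacency)
        labels = np.r_[np.ones(6, dtype=int), np.full(6, 2, dtype=int)]
        A_blocked = network_sortedness(g, Partition(labels))
        rng = np.random.default_rng(1)
        A_rand = np.mean(
            [
                network_sortedness(g, Partition(rng.permutation(labels)))
                for _ in range(20)
            ]
        )
        assert A_blocked > A_rand

    def test_population_relabelling_invariance(self, labelled30):
        g, p = labelled30["graph"], labelled30["partition"]
        swapped = Partition(np.where(p.labels == 1, 2, 1))
        for variant in ("plain", "boundary_corrected"):
            assert network_sortedness(g, p, variant=variant) == pytest.approx(
                network_sortedness(g, swapped, variant=variant), abs=1e-12
            )

    def test_boundary_correction_coincides_on_full_degree_nodes(self):
        g = make_bc_lattice(n_nodes=66)
        p = random_partition(g.N, 0.2, np.random.default_rng(3))
        for i in np.flatnonzero(g.degrees == g.J):
            assert modified_node_sortedness(g, p, int(i)) == pytest.approx(
                node_sortedness(g, p, int(i)), abs=1e-12
            )

    def test_bounds(self, ws1000):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = random_partition(1000, 0.1, rng)
            A = network_sortedness(ws1000, p)
            assert -1.0 <= A <= 1.0


class TestDelta:
    @pytest.mark.parametrize("variant", ["plain", "boundary_corrected"])
    def test_exhaustive_against_recompute(self, labelled30, variant):
        g, p = labelled30["graph"], labelled30["partition"]
        A0 = network_sortedness(g, p, variant=variant)
        pop1 = np.flatnonzero(p.labels == 1)
        pop2 = np.flatnonzero(p.labels == 2)
        for i in pop1:
            for j in pop2:
                d = sortedness_delta(g, p, int(i), int(j), variant=variant)
                lab = p.labels.copy()
                lab[i], lab[j] = lab[j], lab[i]
                A1 = network_sortedness(g, Partition(lab), variant=variant)
                assert d == pytest.approx(A1 - A0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_delta_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = make_ws_graph(30, 4, 0.3, seed=seed)
        p = random_partition(30, 0.2, rng)
        i = int(rng.choice(np.flatnonzero(p.labels == 1)))
        j = int(rng.choice(np.flatnonzero(p.labels == 2)))
        for variant in ("plain", "boundary_corrected"):
            d = sortedness_delta(g, p, i, j, variant=variant)
            lab = p.labels.copy()
            lab[i], lab[j] = lab[j], lab[i]
            exact = network_sortedness(g, Partition(lab), variant=variant) - \
                network_sortedness(g, p, variant=variant)
            assert d == pytest.approx(exact, abs=1e-12)


class TestSelectionPDF:
    def test_uniform_probabilities_sum_to_one(self, labelled30):
        pdf = build_selection_pdf(labelled30["graph"], labelled30["partition"], "uniform")
        for k in (1, 2):
            assert pdf.probs[k].sum() == pytest.approx(1.0)
            assert np.all(pdf.probs[k] > 0)

    @pytest.mark.parametrize("variant", ["radial", "radial_literal"])
    def test_radial_variants_need_coords(self, ring6, variant):
        # the ring fixture carries no embedding
        with pytest.raises(ValueError):
            build_selection_pdf(ring6["graph"], ring6["partition"], variant)

    @pytest.mark.parametrize("variant", ["radial", "radial_literal"])
    def test_radial_variants_on_lattice(self, variant):
        g = make_bc_lattice(n_nodes=66)
        p = random_partition(66, 0.2, np.random.default_rng(0))
        pdf = build_selection_pdf(g, p, variant)
        for k in (1, 2):
            assert pdf.probs[k].sum() == pytest.approx(1.0)

    def test_unknown_variant(self, labelled30):
        with pytest.raises(ValueError):
            build_selection_pdf(labelled30["graph"], labelled30["partition"], "bogus")


class TestSorter:
    def test_forward_monotone_and_terminates(self):
        g = make_ws_graph(200, 8, 0.2, seed=4)
        p0 = random_partition(200, 0.1, np.random.default_rng(4))
        trace = sort_network(g, p0, rng=np.random.default_rng(4))
        vals = np.asarray(trace.sortedness_values)
        assert np.all(np.diff(vals) > 0)
        assert trace.a_final == len(vals) - 1
        # converged: recomputed A of final labels matches the trace tail
        assert network_sortedness(g, Partition(trace.labels_at(trace.a_final))) == \
            pytest.approx(vals[-1], abs=1e-12)

    def test_backward_decreases(self):
        g = make_ws_graph(120, 6, 0.2, seed=5)
        p0 = random_partition(120, 0.1, np.random.default_rng(5))
        fwd = sort_network(g, p0, rng=np.random.default_rng(5))
        sorted_p = Partition(fwd.labels_at(fwd.a_final))
        back = sort_network(
            g, sorted_p, direction="backward", rng=np.random.default_rng(6)
        )
        vals = np.asarray(back.sortedness_values)
        assert np.all(np.diff(vals) < 0)

    def test_population_sizes_preserved(self):
        g = make_ws_graph(100, 6, 0.2, seed=7)
        p0 = random_partition(100, 0.1, np.random.default_rng(7))
        trace = sort_network(g, p0, rng=np.random.default_rng(7))
        for a in (0, trace.a_final // 2, trace.a_final):
            assert np.sum(trace.labels_at(a) == 1) == 10

    def test_seeded_reproducibility(self):
        g = make_ws_graph(100, 6, 0.2, seed=8)
        p0 = random_partition(100, 0.1, np.random.default_rng(8))
        t1 = sort_network(g, p0, seed=11)
        t2 = sort_network(g, p0, seed=11)
        assert t1.accepted_swaps == t2.accepted_swaps

    def test_max_iterations_cap(self):
        g = make_ws_graph(100, 6, 0.2, seed=9)
        p0 = random_partition(100, 0.1, np.random.default_rng(9))
        trace = sort_network(g, p0, seed=1, max_iterations=3)
        assert trace.a_final == 3

    def test_labels_at_out_of_range(self):
        g = make_ws_graph(60, 4, 0.2, seed=10)
        p0 = random_partition(60, 0.1, np.random.default_rng(10))
        trace = sort_network(g, p0, seed=2, max_iterations=2)
        with pytest.raises(IndexError):
            trace.labels_at(trace.a_final + 1)

    def test_three_populations_rejected(self):
        g = make_ws_graph(30, 4, 0.2, seed=11)
        labels = np.tile([1, 2, 3], 10)
        with pytest.raises(ValueError):
            sort_network(g, Partition(labels), seed=0)
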