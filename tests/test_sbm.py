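"""MDL objective, agglomerative fitting, exhaustive oracle, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import gldm
from gldm.sbm import (
    ComparabilityError,
    PartitionError,
    _set_partitions,
    compare_models,
    description_length,
    exhaustive_oracle,
    fit_sbm,
    merge_dendrogram,
    quantile_bin_edges,
)
from tests.conftest import random_layered_graph, toy_graph


def longhand_dl(graph, partition, n_bins=8):
    """Independent longhand evaluation of the description-length formula,
    written with explicit python loops (no shared code with the package
    implementation beyond the bin edges)."""
    nodes = list(graph.nodes)
    pos = {int(n): i for i, n in enumerate(nodes)}
    b = np.asarray(partition)
    b = b - b.min()
    B = b.max() + 1
    n_r = [int((b == r).sum()) for r in range(B)]
    edges = [
        (pos[int(r.j)], pos[int(r.k)], float(r.w_les), float(r.w_def))
        for r in graph.edges.itertuples(index=False)
    ]
    # adjacency term
    m = {}
    for j, k, _, _ in edges:
        r, s = b[j], b[k]
        m[(r, s)] = m.get((r, s), 0) + 1
        m[(s, r)] = m.get((s, r), 0) + 1
    s_adj = 0.0
    for (r, s), cnt in m.items():
        s_adj -= 0.5 * cnt * np.log(cnt / (n_r[r] * n_r[s]))
    E = len(edges)
    slots = B * (B + 1) / 2
    s_adj += float(gammaln(slots + E) - gammaln(E + 1) - gammaln(slots))
    # weight channels with global quantile bins
    def channel(idx):
        edges_w = [e[idx] for e in edges]
        cuts = quantile_bin_edges(np.array(edges_w), n_bins)
        total = 0.0
        pair_bins = {}
        for (j, k, *_), w in zip(edges, edges_w):
            r, s = sorted((b[j], b[k]))
            q = int(np.searchsorted(cuts, w, side="right"))
            pair_bins.setdefault((r, s), []).append(q)
        for bins in pair_bins.values():
            mm = len(bins)
            for q in set(bins):
                c = bins.count(q)
                total -= c * np.log(c / mm)
            total += float(
                gammaln(mm + n_bins) - gammaln(mm + 1) - gammaln(n_bins)
            )
        return total

    s_wles, s_wdef = channel(2), channel(3)
    s_part = len(nodes) * np.log(B)
    return s_adj + s_wles + s_wdef + s_part


class TestDescriptionLength:
    def test_single_block_partition_prior_zero(self):
        g = random_layered_graph(6, seed=0)
        st = description_length(g, np.ones(6, dtype=int))
        assert st.dl_components["partition_prior"] == pytest.approx(0.0)

    def test_constant_weights_zero_entropy_terms(self):
        rows = [(1, 2, 2, 0.1, 0.5), (2, 3, 2, 0.1, 0.5), (1, 3, 2, 0.1, 0.5)]
        g = toy_graph(rows)
        st = description_length(g, [1, 1, 2])
        # all weights in one bin: only the count-declaration cost remains
        expected_comb = sum(
            float(gammaln(m + 8) - gammaln(m + 1) - gammaln(8)) for m in (1, 2)
        )
        assert st.dl_components["weights_lesion"] == pytest.approx(expected_comb)
        assert st.dl_components["weights_deficit"] == pytest.approx(expected_comb)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_longhand_oracle(self, seed):
        g = random_layered_graph(6, seed=seed, p=0.7)
        rng = np.random.default_rng(seed)
        part = rng.integers(0, 3, 6)
        part = np.unique(part, return_inverse=True)[1]  # contiguous
        st = description_length(g, part)
        assert st.dl_total == pytest.approx(longhand_dl(g, part), abs=1e-9)

    def test_total_equals_component_sum(self):
        g = random_layered_graph(7, seed=3)
        st = description_length(g, np.zeros(7, dtype=int))
        assert st.dl_total == pytest.approx(sum(st.dl_components.values()))

    def test_empty_block_rejected(self):
        g = random_layered_graph(5, seed=1)
        with pytest.raises(PartitionError):
            description_length(g, [0, 0, 2, 2, 2])  # block 1 declared empty

    def test_wrong_length_rejected(self):
        g = random_layered_graph(5, seed=1)
        with pytest.raises(PartitionError):
            description_length(g, [0, 1])

    def test_invariant_to_block_label_permutation(self):
        g = random_layered_graph(8, seed=4, p=0.6)
        a = np.array([0, 0, 1, 1, 2, 2, 0, 1])
        relabelled = np.array([2, 2, 0, 0, 1, 1, 2, 0])
        assert description_length(g, a).dl_total == pytest.approx(
            description_length(g, relabelled).dl_total
        )

    def test_invariant_to_node_relabelling(self):
        g = random_layered_graph(6, seed=9, p=0.8)
        part = np.array([0, 0, 0, 1, 1, 1])
        mapping = {1: 4, 2: 6, 3: 1, 4: 3, 5: 2, 6: 5}
        edges2 = g.edges.copy()
        jj = edges2["j"].map(mapping)
        kk = edges2["k"].map(mapping)
        edges2["j"], edges2["k"] = np.minimum(jj, kk), np.maximum(jj, kk)
        g2 = gldm.LayeredGraph(nodes=g.nodes, edges=edges2, n_patients=g.n_patients)
        part2 = np.empty(6, dtype=int)
        for old, new in mapping.items():
            part2[new - 1] = part[old - 1]
        assert description_length(g, part).dl_total == pytest.approx(
            description_length(g2, part2).dl_total
        )


class TestSetPartitions:
    def test_bell_numbers(self):
        assert sum(1 for _ in _set_partitions(4)) == 15
        assert sum(1 for _ in _set_partitions(8)) == 4140

    def test_single_element(self):
        parts = list(_set_partitions(1))
        assert len(parts) == 1 and parts[0].tolist() == [0]


class TestFitSbm:
    def test_two_cliques_with_distinct_weights_recovered(self):
        rows = []
        for grp, w_les, w_def in (([1, 2, 3, 4], 0.2, 2.0), ([5, 6, 7, 8], 0.04, 0.1)):
            for i, j in zip(*np.triu_indices(4, k=1)):
                rows.append((grp[i], grp[j], 4, w_les, w_def))
        g = toy_graph(rows)
        st = fit_sbm(g, seed=0)
        orc = exhaustive_oracle(g)
        assert st.dl_total == pytest.approx(orc.dl_total, abs=1e-9)
        assert st.b == 2
        blocks = dict(zip(st.nodes.tolist(), st.partition.tolist()))
        assert len({blocks[n] for n in (1, 2, 3, 4)}) == 1
        assert len({blocks[n] for n in (5, 6, 7, 8)}) == 1
        assert blocks[1] != blocks[5]

    def test_iid_graph_prefers_single_block(self):
        single = 0
        for seed in range(20):
            g = random_layered_graph(8, seed=100 + seed, p=0.5)
            st = fit_sbm(g, seed=seed)
            single += st.b == 1
        assert single > 10

    def test_deterministic_for_fixed_seed(self):
        g = random_layered_graph(10, seed=2, p=0.5)
        a = fit_sbm(g, seed=7)
        b = fit_sbm(g, seed=7)
        assert a.dl_total == b.dl_total
        assert np.array_equal(a.partition, b.partition)

    def test_attains_oracle_on_random_graphs(self):
        """Heuristic fit reaches the exhaustive global optimum on >= 50
        random graphs with <= 8 nodes."""
        matches = 0
        for seed in range(50):
            n = 5 + seed % 4
            g = random_layered_graph(n, seed=seed, p=0.5)
            orc = exhaustive_oracle(g)
            st = fit_sbm(g, seed=seed)
            assert st.dl_total >= orc.dl_total - 1e-9  # oracle is a lower bound
            matches += abs(st.dl_total - orc.dl_total) < 1e-9
        assert matches == 50

    def test_accepted_moves_strictly_decrease_dl(self):
        """Within each agglomerative level, every accepted reassignment move
        strictly lowers the description length."""
        g = random_layered_graph(10, seed=6, p=0.6)
        st = fit_sbm(g, seed=3)
        n_moves = 0
        for level_moves in st.config["dl_trace"]:
            assert all(
                b < a - 1e-12 for a, b in zip(level_moves, level_moves[1:])
            )
            n_moves += max(0, len(level_moves) - 1)
        assert len(st.config["dl_trace"]) >= 1

    def test_empty_graph_rejected(self):
        g = toy_graph([(1, 2, 2, 0.1, 0.0)])
        g.edges = g.edges.iloc[:0]
        with pytest.raises(ValueError):
            fit_sbm(g, seed=0)

    def test_oracle_size_guard(self):
        g = random_layered_graph(9, seed=0)
        with pytest.raises(ValueError):
            exhaustive_oracle(g, n_max=8)


class TestCompareModels:
    def test_printed_worked_comparisons(self):
        c = compare_models(476362.0, 725748.0)
        assert c.delta == pytest.approx(249386.0)
        assert c.odds_label == "e249386"
        c2 = compare_models(451868.0, 699072.0)
        assert c2.delta == pytest.approx(247204.0)
        assert c2.odds_label == "e247204"

    def test_equal_entropies(self):
        c = compare_models(100.0, 100.0)
        assert c.delta == 0.0
        assert c.odds_label == "e0"

    def test_mismatched_edge_sets_rejected(self):
        g1 = random_layered_graph(6, seed=1, p=0.6)
        g2 = random_layered_graph(6, seed=2, p=0.6)
        s1, s2 = fit_sbm(g1, seed=0), fit_sbm(g2, seed=0)
        with pytest.raises(ComparabilityError):
            compare_models(s1, s2)

    def test_blockstates_compare_via_dl(self):
        g = random_layered_graph(6, seed=1, p=0.6)
        s1 = fit_sbm(g, seed=0)
        s2 = description_length(g, np.zeros(6, dtype=int))
        c = compare_models(s1, s2)
        assert c.delta == pytest.approx(s2.dl_total - s1.dl_total)


def test_merge_dendrogram_newick_shape():
    g = random_layered_graph(8, seed=11, p=0.7)
    st = fit_sbm(g, seed=1)
    nwk = merge_dendrogram(g, st)
    assert nwk.endswith(";")
    assert nwk.count("B") == st.b
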