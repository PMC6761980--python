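"""Graph model, GFA ingestion and topology generators."""

import random

import pytest

from graphaln.graph import (
    GraphError,
    SequenceGraph,
    add_reverse_complement,
    from_gfa,
    from_tsv,
    generate_linear,
    generate_snp,
    generate_tangle,
    generate_twopath,
    mutate_sequence,
    normalize_singletons,
    random_sequence,
    reverse_complement,
    sample_path,
    to_gfa,
    to_tsv,
    topological_order,
    _debruijn_kmer_graph,
)


def edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[j - 1] + 1))
        prev = cur
    return prev[-1]


class TestGfa:
    def test_single_segment_expands_to_chain(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tx\tACG\n")
        g = from_gfa(p)
        assert g.node_count == 3 and g.edge_count == 2
        assert g.labels == list("ACG")
        g.check_consistent()

    def test_link_joins_last_to_first(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tX\tAC\nS\tY\tGT\nL\tX\t+\tY\t+\t0M\n")
        g = from_gfa(p)
        assert g.node_count == 4 and g.edge_count == 3
        c = g.labels.index("C")
        gg = g.labels.index("G")
        assert gg in g.out_edges[c]

    def test_self_link_makes_cycle(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tX\tAC\nL\tX\t+\tX\t+\t0M\n")
        g = from_gfa(p)
        # edge from 'C' back to 'A': enumerate edges after expansion
        edges = {(u, v) for u in range(g.node_count) for v in g.out_edges[u]}
        assert (1, 0) in edges and (0, 1) in edges
        assert topological_order(g) is None

    def test_minus_orientation_materializes_reverse_complement(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tX\tAC\nS\tY\tGG\nL\tX\t+\tY\t-\t0M\n")
        g = from_gfa(p)
        # Y- is CC; the link goes from X's 'C' to the first 'C' of Y-
        assert g.node_count == 6  # X(2) + Y+(2) + Y-(2)
        assert sorted(g.labels) == sorted("ACGGCC")
        g.check_consistent()

    @pytest.mark.parametrize(
        "content,message",
        [
            ("S\tX\tAC\nS\tY\tG\nL\tX\t+\tY\t+\t5M\n", "overlap"),
            ("S\tX\t*\n", "sequence"),
            ("S\tX\tAZ\n", "alphabet"),
        ],
    )
    def test_dialect_errors(self, tmp_path, content, message):
        p = tmp_path / "g.gfa"
        p.write_text(content)
        with pytest.raises(GraphError, match=message):
            from_gfa(p)

    def test_iupac_policy_maps_to_n(self, tmp_path):
        p = tmp_path / "g.gfa"
        p.write_text("S\tX\tARG\n")
        g = from_gfa(p, iupac_as_n=True)
        assert g.labels == ["A", "N", "G"]

    def test_gfa_roundtrip_via_1bp_segments(self, tmp_path):
        g = generate_snp("ACGTACGT", snp_rate=0.5, seed=3)
        out = tmp_path / "out.gfa"
        to_gfa(g, out)
        g2 = from_gfa(out)
        assert g2.labels == g.labels
        assert [sorted(a) for a in g2.out_edges] == [sorted(a) for a in g.out_edges]

    def test_tsv_roundtrip(self, tmp_path):
        g = generate_twopath("ACGT", seed=1)
        out = tmp_path / "g.tsv"
        to_tsv(g, out)
        g2 = from_tsv(out)
        assert g2.labels == g.labels and g2.out_edges == g.out_edges


class TestGenerators:
    def test_linear_chain(self):
        g = generate_linear("ACGT")
        assert g.node_count == 4 and g.edge_count == 3
        g = generate_linear("A")
        assert g.node_count == 1 and g.edge_count == 0
        with pytest.raises(GraphError):
            generate_linear("")

    def test_doubled_linear_counts(self):
        g = add_reverse_complement(generate_linear(random_sequence(10000, seed=5)))
        assert g.node_count == 20000 and g.edge_count == 19998

    def test_snp_rate_zero_is_linear(self):
        a = generate_snp("ACGTACGT", snp_rate=0.0, seed=1)
        b = generate_linear("ACGTACGT")
        assert a.labels == b.labels and a.out_edges == b.out_edges

    def test_snp_rate_one_bubbles_everywhere(self):
        g = generate_snp("ACG", snp_rate=1.0, seed=2)
        assert g.node_count == 6
        # middle bubble nodes have 2 in- and 2 out-edges
        middles = [v for v in range(g.node_count)
                   if g.in_edges[v] and g.out_edges[v]]
        assert middles and all(
            len(g.in_edges[v]) == 2 and len(g.out_edges[v]) == 2 for v in middles
        )
        # alternative label always differs from reference at the same position
        g.check_consistent()

    def test_snp_deterministic(self):
        a = generate_snp("ACGTACGTAC", snp_rate=0.5, seed=9)
        b = generate_snp("ACGTACGTAC", snp_rate=0.5, seed=9)
        assert a.labels == b.labels and a.out_edges == b.out_edges

    def test_snp_rate_validation(self):
        with pytest.raises(GraphError):
            generate_snp("ACGT", snp_rate=1.5)

    def test_twopath_structure(self):
        g = generate_twopath("ACG", seed=0)
        assert g.node_count == 6 and g.edge_count == 8
        for pos in (1, 2):
            for c in (0, 1):
                assert len(g.in_edges[c * 3 + pos]) == 2
        assert topological_order(g) is not None
        g1 = generate_twopath("A")
        assert g1.node_count == 2 and g1.edge_count == 0

    def test_twopath_duplicate_labels(self):
        g = generate_twopath("ACG", labels="duplicate")
        assert g.labels == list("ACGACG")

    def test_tangle_repeat_collapses_to_self_loop(self):
        g = generate_tangle("AAAA", k=2)
        assert g.node_count == 1 and g.labels == ["A"]
        assert g.out_edges[0] == [0]

    def test_tangle_unique_kmers_give_chain(self):
        seq = "ACGTGCTA"  # all 3-mers distinct
        g = generate_tangle(seq, k=3)
        assert "".join(g.labels) == seq
        assert all(len(o) <= 1 for o in g.out_edges)

    def test_tangle_validation(self):
        with pytest.raises(GraphError):
            generate_tangle("ACGT", k=1)
        with pytest.raises(GraphError):
            generate_tangle("AC", k=3)

    @pytest.mark.parametrize("seed", range(12))
    def test_tangle_walk_labels_match_debruijn(self, seed):
        """Exhaustive small-case check: length-L walk labels of the tangle
        graph equal the length-L windows of de Bruijn walk spellings."""
        rng = random.Random(seed)
        n = rng.randint(5, 12)
        k = rng.choice([2, 3])
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        g = generate_tangle(seq, k)
        g.check_consistent()
        L = 5
        kmers, out = _debruijn_kmer_graph(seq, k)

        debruijn_windows: set[str] = set()

        def walk_db(node, spelled, depth):
            for i in range(len(spelled) - L + 1):
                debruijn_windows.add(spelled[i : i + L])
            if depth == 0:
                return
            for nxt in out[node]:
                walk_db(nxt, spelled + kmers[nxt][-1], depth - 1)

        for v in range(len(kmers)):
            walk_db(v, kmers[v], L + 1)

        graph_labels: set[str] = set()

        def walk_g(node, spelled):
            if len(spelled) == L:
                graph_labels.add(spelled)
                return
            for nxt in g.out_edges[node]:
                walk_g(nxt, spelled + g.labels[nxt])

        for v in range(g.node_count):
            walk_g(v, g.labels[v])

        assert graph_labels == debruijn_windows


class TestTransforms:
    def test_reverse_complement_doubling(self):
        g = generate_linear("AC")
        d = add_reverse_complement(g)
        assert d.node_count == 4 and d.edge_count == 2
        assert sorted(d.labels) == sorted("ACGT")
        # the copy spells the reverse complement: a G->T chain
        (u,) = [v for v in (2, 3) if d.out_edges[v]]
        assert d.labels[u] == "G" and d.labels[d.out_edges[u][0]] == "T"
        dd = add_reverse_complement(d)
        assert dd.node_count == 8  # disjoint union: no deduplication
        dd.check_consistent()

    @pytest.mark.parametrize("seed", range(5))
    def test_doubling_exactly_doubles(self, seed):
        rng = random.Random(seed)
        from conftest import random_graph

        g = random_graph(rng)
        d = add_reverse_complement(g)
        assert d.node_count == 2 * g.node_count
        assert d.edge_count == 2 * g.edge_count
        d.check_consistent()

    def test_topological_order_chain_and_cycle(self):
        g = generate_linear("ACGT")
        order = topological_order(g)
        pos = {v: i for i, v in enumerate(order)}
        assert all(pos[u] < pos[v] for u in range(4) for v in g.out_edges[u])
        c = SequenceGraph()
        c.add_node("A"), c.add_node("C")
        c.add_edge(0, 1), c.add_edge(1, 0)
        assert topological_order(c) is None

    def test_topological_order_twopath(self):
        g = generate_twopath("ACGTAC")
        order = topological_order(g)
        pos = {v: i for i, v in enumerate(order)}
        assert all(
            pos[u] < pos[v] for u in range(g.node_count) for v in g.out_edges[u]
        )

    def test_normalize_singletons(self):
        g = SequenceGraph()
        for _ in range(5):
            g.add_node("A")
        assert normalize_singletons(g).node_count == 1
        con = generate_linear("ACGT")
        norm = normalize_singletons(con)
        assert norm.labels == con.labels and norm.out_edges == con.out_edges
        # mixed: isolated collapse per label, connected part untouched
        mix = generate_linear("ACG")
        for lab in "TTGG":
            mix.add_node(lab)
        out = normalize_singletons(mix)
        assert out.node_count == 3 + 2
        assert out.node_count <= 2 * out.edge_count + 4

    def test_reverse_complement_string(self):
        assert reverse_complement("ACGTN") == "NACGT"


class TestSampling:
    def test_linear_full_walk(self):
        g = generate_linear("ACGTT")
        p = sample_path(g, 5, seed=1)
        assert p.sequence == "ACGTT" and p.nodes == [0, 1, 2, 3, 4]

    def test_self_loop_repeats(self):
        g = SequenceGraph()
        g.add_node("A")
        g.add_edge(0, 0)
        p = sample_path(g, 5, seed=0)
        assert p.nodes == [0] * 5 and p.sequence == "AAAAA"

    @pytest.mark.parametrize("seed", range(5))
    def test_sequence_matches_labels_and_edges(self, seed, rng):
        from conftest import random_graph_with_loops

        g = random_graph_with_loops(random.Random(seed))
        p = sample_path(g, 8, seed=seed)
        assert p.sequence == "".join(g.labels[v] for v in p.nodes)
        assert all(b in g.out_edges[a] for a, b in zip(p.nodes, p.nodes[1:]))

    def test_dead_end_raises(self):
        g = generate_linear("AC")
        with pytest.raises(GraphError):
            sample_path(g, 10, seed=0)

    def test_mutate_identity_and_all_deletions(self):
        assert mutate_sequence("ACGT", 0, 0, 0, seed=1) == ("ACGT", 0)
        out, edits = mutate_sequence("ACGT", 0, 0, 1.0, seed=1)
        assert out == "" and edits == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_mutation_edit_bound(self, seed):
        seq = random_sequence(60, seed=seed)
        out, edits = mutate_sequence(seq, 0.05, 0.05, 0.05, seed=seed)
        assert edit_distance(seq, out) <= edits

    def test_rates_sum_validation(self):
        with pytest.raises(GraphError):
            mutate_sequence("ACGT", 0.5, 0.4, 0.3)
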