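"""Sequence graphs: one character per node, directed edges.

A sequence graph is a directed graph ``G = (V, E, sigma)`` where every node
carries a single character from an alphabet (``ACGT`` by default, plus ``N``
under the lenient policy).  A path -- repeated nodes allowed -- spells the
concatenation of its node labels.  This is the common denominator of
variation graphs, de Bruijn graphs and assembly string graphs once segment
sequences are expanded character by character.

This module holds the data model, GFA 1.0 ingestion/export, the benchmark
topology generators (linear / SNP / twopath / tangle), reverse-complement
doubling, and utilities to sample reads from graph paths.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

DNA = "ACGT"
DNA_N = "ACGTN"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# IUPAC ambiguity codes collapsed to N under the lenient alphabet policy.
_IUPAC = set("RYSWKMBDHVN")


class GraphError(ValueError):
    """Malformed graph input or unsupported GFA dialect."""


class CyclicGraphError(GraphError):
    """Raised when an operation requiring a DAG meets a cycle."""


@dataclass
class SequenceGraph:
    """Directed node-labeled graph with dense 0-based node ids.

    Attributes
    ----------
    labels:
        ``labels[i]`` is the single character of node ``i``.
    out_edges, in_edges:
        Adjacency lists; mutually consistent (``j in out_edges[i]`` iff
        ``i in in_edges[j]``) and duplicate-free, since the edge set is a
        mathematical set.
    segment_map:
        Optional provenance: per node ``(segment name, offset, strand)``
        pointing back to the GFA segment it was expanded from.
    """

    labels: list[str] = field(default_factory=list)
    out_edges: list[list[int]] = field(default_factory=list)
    in_edges: list[list[int]] = field(default_factory=list)
    segment_map: Optional[list[tuple[str, int, str]]] = None

    # -- construction -----------------------------------------------------

    def add_node(self, label: str, provenance: Optional[tuple[str, int, str]] = None) -> int:
        if len(label) != 1 or label not in DNA_N:
            raise GraphError(f"node label must be one of {DNA_N!r}, got {label!r}")
        self.labels.append(label)
        self.out_edges.append([])
        self.in_edges.append([])
        if provenance is not None:
            if self.segment_map is None:
                self.segment_map = [("", -1, "+")] * (len(self.labels) - 1)
            self.segment_map.append(provenance)
        elif self.segment_map is not None:
            self.segment_map.append(("", -1, "+"))
        return len(self.labels) - 1

    def add_edge(self, u: int, v: int) -> None:
        if v not in self.out_edges[u]:
            self.out_edges[u].append(v)
            self.in_edges[v].append(u)

    # -- basic queries -----------------------------------------------------

    @property
    def node_count(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        return sum(len(a) for a in self.out_edges)

    def check_consistent(self) -> None:
        """Assert mutual adjacency consistency and label validity."""
        n = self.node_count
        for i, outs in enumerate(self.out_edges):
            if len(set(outs)) != len(outs):
                raise GraphError(f"duplicate out-edge at node {i}")
            for j in outs:
                if not 0 <= j < n or i not in self.in_edges[j]:
                    raise GraphError(f"edge ({i},{j}) not mirrored in in_edges")
        for j, ins in enumerate(self.in_edges):
            if len(set(ins)) != len(ins):
                raise GraphError(f"duplicate in-edge at node {j}")
            for i in ins:
                if j not in self.out_edges[i]:
                    raise GraphError(f"in-edge ({i},{j}) not mirrored in out_edges")
        for i, c in enumerate(self.labels):
            if c not in DNA_N:
                raise GraphError(f"label {c!r} at node {i} outside alphabet")


class PathSample(NamedTuple):
    """A sampled walk: node ids (repeats allowed) and the spelled sequence."""

    nodes: list[int]
    sequence: str


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------


def _apply_alphabet_policy(seq: str, iupac_as_n: bool) -> str:
    seq = seq.upper()
    out = []
    for c in seq:
        if c in DNA:
            out.append(c)
        elif iupac_as_n and c in _IUPAC:
            out.append("N")
        else:
            raise GraphError(
                f"character {c!r} outside alphabet {DNA!r}"
                + ("" if iupac_as_n else " (use iupac_as_n=True to map IUPAC codes to N)")
            )
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def from_gfa(path, iupac_as_n: bool = False) -> SequenceGraph:
    """Load a GFA 1.0 file into a character-per-node :class:`SequenceGraph`.

    Each segment of length L expands to a chain of L single-character nodes.
    An L-line ``X o1 Y o2 0M`` connects the last character of X in orientation
    ``o1`` to the first character of Y in orientation ``o2``.  A ``-``
    orientation refers to the reverse-complement copy of the segment, which is
    materialized only for segments actually referenced with ``-``.

    Only overlap ``0M`` or ``*`` is supported: the graphs handled here are
    overlap-free node-labeled graphs (de Bruijn overlap removal is done by the
    tangle generator itself, not at GFA level).
    """
    segments: dict[str, str] = {}
    links: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise GraphError(f"{path}:{lineno}: malformed S-line")
                name, seq = fields[1], fields[2]
                if seq == "*" or not seq:
                    raise GraphError(f"{path}:{lineno}: segment {name!r} has no sequence")
                segments[name] = _apply_alphabet_policy(seq, iupac_as_n)
            elif tag == "L":
                if len(fields) < 6:
                    raise GraphError(f"{path}:{lineno}: malformed L-line")
                src, so, dst, do, overlap = fields[1:6]
                if overlap not in ("0M", "*"):
                    raise GraphError(
                        f"{path}:{lineno}: unsupported overlap {overlap!r} (only 0M or *)"
                    )
                if so not in "+-" or do not in "+-":
                    raise GraphError(f"{path}:{lineno}: bad orientation")
                links.append((src, so, dst, do))
            # H, P and other lines are ignored.

    g = SequenceGraph(segment_map=[])
    # chain node-id ranges per (segment, strand); '-' copies made lazily
    chains: dict[tuple[str, str], list[int]] = {}

    def chain(name: str, strand: str) -> list[int]:
        key = (name, strand)
        if key not in chains:
            if name not in segments:
                raise GraphError(f"link references unknown segment {name!r}")
            seq = segments[name] if strand == "+" else reverse_complement(segments[name])
            ids = [g.add_node(c, (name, i, strand)) for i, c in enumerate(seq)]
            for a, b in zip(ids, ids[1:]):
                g.add_edge(a, b)
            chains[key] = ids
        return chains[key]

    for name in segments:
        chain(name, "+")
    for name, strand in {(s, o) for s, o, _, _ in links} | {(d, o) for _, _, d, o in links}:
        chain(name, strand)
    for src, so, dst, do in links:
        g.add_edge(chain(src, so)[-1], chain(dst, do)[0])
    return g


def to_gfa(g: SequenceGraph, path) -> None:
    """Export as GFA 1.0 with one 1-bp segment per node (debug format)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for i, c in enumerate(g.labels):
            fh.write(f"S\t{i}\t{c}\n")
        for u, outs in enumerate(g.out_edges):
            for v in outs:
                fh.write(f"L\t{u}\t+\t{v}\t+\t0M\n")


def to_tsv(g: SequenceGraph, path) -> None:
    """Internal node-graph TSV: ``N id label`` and ``E from to`` lines."""
    with open(path, "w") as fh:
        for i, c in enumerate(g.labels):
            fh.write(f"N\t{i}\t{c}\n")
        for u, outs in enumerate(g.out_edges):
            for v in outs:
                fh.write(f"E\t{u}\t{v}\n")


def from_tsv(path) -> SequenceGraph:
    g = SequenceGraph()
    edges = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "N":
                g.add_node(fields[2])
            elif fields[0] == "E":
                edges.append((int(fields[1]), int(fields[2])))
    for u, v in edges:
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Benchmark topology generators
# ---------------------------------------------------------------------------


def generate_linear(seq: str) -> SequenceGraph:
    """Linear chain of nodes spelling ``seq`` (sequence-to-sequence case)."""
    if not seq:
        raise GraphError("empty sequence")
    g = SequenceGraph()
    ids = [g.add_node(c) for c in seq.upper()]
    for a, b in zip(ids, ids[1:]):
        g.add_edge(a, b)
    return g


def generate_snp(seq: str, snp_rate: float = 0.1, seed: int = 0) -> SequenceGraph:
    """Linear chain with random 2-node SNP bubbles.

    At each position, with probability ``snp_rate`` (default one SNP per 10 bp)
    an alternative node with a different random base is wired in parallel with
    the reference node: same predecessors, same successors.  The reference node
    is never removed.
    """
    if not 0 <= snp_rate <= 1:
        raise GraphError(f"snp_rate must be in [0,1], got {snp_rate}")
    if not seq:
        raise GraphError("empty sequence")
    rng = random.Random(seed)
    g = SequenceGraph()
    prev: list[int] = []
    for c in seq.upper():
        ref = g.add_node(c)
        layer = [ref]
        if rng.random() < snp_rate:
            alt_base = rng.choice([b for b in DNA if b != c])
            layer.append(g.add_node(alt_base))
        for p in prev:
            for q in layer:
                g.add_edge(p, q)
        prev = layer
    return g


def generate_twopath(seq: str, labels: str = "random", seed: int = 0) -> SequenceGraph:
    """Worst-case graph for column merging: every non-first node has in-degree 2.

    Two parallel chains; chain 0 spells ``seq``, chain 1 carries random labels
    (``labels="random"``) or duplicates ``seq`` (``labels="duplicate"``).
    Cross edges run from both position-(i-1) nodes to both position-i nodes,
    forcing a merge at every node.
    """
    if not seq:
        raise GraphError("empty sequence")
    if labels not in ("random", "duplicate"):
        raise GraphError(f"labels policy must be 'random' or 'duplicate', got {labels!r}")
    rng = random.Random(seed)
    seq = seq.upper()
    g = SequenceGraph()
    top = [g.add_node(c) for c in seq]
    second = seq if labels == "duplicate" else "".join(rng.choice(DNA) for _ in seq)
    bot = [g.add_node(c) for c in second]
    for i in range(1, len(seq)):
        for p in (top[i - 1], bot[i - 1]):
            for q in (top[i], bot[i]):
                g.add_edge(p, q)
    return g


def _debruijn_kmer_graph(seq: str, k: int) -> tuple[list[str], list[list[int]]]:
    """Node-centric de Bruijn graph of one sequence: distinct k-mers, edges
    between consecutive k-mers of ``seq``."""
    kmers: dict[str, int] = {}
    order: list[str] = []
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km not in kmers:
            kmers[km] = len(order)
            order.append(km)
    out: list[list[int]] = [[] for _ in order]
    for i in range(len(seq) - k):
        u, v = kmers[seq[i : i + k]], kmers[seq[i + 1 : i + k + 1]]
        if v not in out[u]:
            out[u].append(v)
    return order, out


def generate_tangle(seq: str, k: int = 11) -> SequenceGraph:
    """De-Bruijn-based "tangle" graph: unitig compaction plus overlap trimming.

    Builds the k-mer de Bruijn graph of ``seq``, compacts maximal
    non-branching paths into unitigs, removes the (k-1)-overlaps by deleting
    the last k-1 characters of every non-tip node (tip = out-degree 0), and
    finally expands unitig strings into character chains.  Unitigs whose
    string would be emptied by trimming are removed and their neighbors
    reconnected, which preserves walk labels.  Small ``k`` on a repetitive
    sequence yields a highly cyclic, tangled graph.
    """
    if k < 2:
        raise GraphError(f"k must be >= 2, got {k}")
    seq = seq.upper()
    if len(seq) < k:
        raise GraphError("sequence shorter than k")
    kmer_strs, out = _debruijn_kmer_graph(seq, k)
    n = len(kmer_strs)

    # unitig compaction: node v extends its predecessor's unitig iff it has
    # exactly one in-neighbor u and u has out-degree 1
    unitigs: list[list[int]] = []  # runs of k-mer node ids
    uid_of: dict[int, int] = {}
    in_nbr: list[list[int]] = [[] for _ in range(n)]
    for u in range(n):
        for v in out[u]:
            in_nbr[v].append(u)

    def extends_previous(v: int) -> bool:
        return len(in_nbr[v]) == 1 and len(out[in_nbr[v][0]]) == 1

    visited = [False] * n
    for v in range(n):
        if visited[v] or extends_previous(v):
            continue
        run = [v]
        visited[v] = True
        cur = v
        while len(out[cur]) == 1:
            nxt = out[cur][0]
            if visited[nxt] or not extends_previous(nxt):
                break
            run.append(nxt)
            visited[nxt] = True
            cur = nxt
        uid = len(unitigs)
        unitigs.append(run)
        for node in run:
            uid_of[node] = uid
    # isolated cycles where every node extends its predecessor: break arbitrarily
    for v in range(n):
        if not visited[v]:
            run = [v]
            visited[v] = True
            cur = out[v][0]
            while cur != v:
                run.append(cur)
                visited[cur] = True
                cur = out[cur][0]
            uid = len(unitigs)
            unitigs.append(run)
            for node in run:
                uid_of[node] = uid

    # unitig strings (overlap-merged) and unitig-level edges
    ustr = []
    for run in unitigs:
        s = kmer_strs[run[0]]
        for node in run[1:]:
            s += kmer_strs[node][-1]
        ustr.append(s)
    uout: list[list[int]] = [[] for _ in unitigs]
    for uid, run in enumerate(unitigs):
        for v in out[run[-1]]:
            w = uid_of[v]
            # only edges leaving the unitig (or genuine self-loops)
            if v == run[0] or w != uid:
                if w not in uout[uid]:
                    uout[uid].append(w)

    # overlap trimming: non-tip (out-degree > 0) unitigs lose their last k-1
    # characters; emptied unitigs are removed with neighbor reconnection
    trimmed: list[Optional[str]] = []
    for uid, s in enumerate(ustr):
        if len(uout[uid]) == 0:  # tip keeps full sequence
            trimmed.append(s)
        else:
            t = s[: -(k - 1)]
            trimmed.append(t if t else None)
    # transitive closure over removed (None) unitigs
    def successors(u: int, seen: frozenset[int]) -> list[int]:
        res: list[int] = []
        for v in uout[u]:
            if trimmed[v] is not None:
                if v not in res:
                    res.append(v)
            elif v not in seen:
                for w in successors(v, seen | {v}):
                    if w not in res:
                        res.append(w)
        return res

    g = SequenceGraph()
    first: dict[int, int] = {}
    last: dict[int, int] = {}
    for uid, s in enumerate(trimmed):
        if s is None:
            continue
        ids = [g.add_node(c) for c in s]
        for a, b in zip(ids, ids[1:]):
            g.add_edge(a, b)
        first[uid], last[uid] = ids[0], ids[-1]
    for uid, s in enumerate(trimmed):
        if s is None:
            continue
        for w in successors(uid, frozenset({uid})):
            g.add_edge(last[uid], first[w])
    return g


def add_reverse_complement(g: SequenceGraph) -> SequenceGraph:
    """Disjoint union of ``g`` and its reverse complement.

    Labels are complemented (N stays N) and every edge is reversed in the
    copy; node and edge counts exactly double.  Mimics a bidirected graph so
    reads from either strand align to some path.
    """
    out = SequenceGraph(
        labels=list(g.labels),
        out_edges=[list(a) for a in g.out_edges],
        in_edges=[list(a) for a in g.in_edges],
        segment_map=list(g.segment_map) if g.segment_map is not None else None,
    )
    n = g.node_count
    for i, c in enumerate(g.labels):
        prov = None
        if g.segment_map is not None:
            name, off, strand = g.segment_map[i]
            prov = (name, off, "-" if strand == "+" else "+")
        out.add_node(_COMPLEMENT[c], prov)
    for u, outs in enumerate(g.out_edges):
        for v in outs:
            out.add_edge(n + v, n + u)
    return out


# ---------------------------------------------------------------------------
# Structure operations
# ---------------------------------------------------------------------------


def topological_order(g: SequenceGraph) -> Optional[list[int]]:
    """Kahn's algorithm: a total order with all edges forward, or ``None``
    if the graph is cyclic."""
    indeg = [len(a) for a in g.in_edges]
    stack = [v for v, d in enumerate(indeg) if d == 0]
    order: list[int] = []
    while stack:
        v = stack.pop()
        order.append(v)
        for y in g.out_edges[v]:
            indeg[y] -= 1
            if indeg[y] == 0:
                stack.append(y)
    return order if len(order) == g.node_count else None


def is_acyclic(g: SequenceGraph) -> bool:
    return topological_order(g) is not None


def pseudo_topological_order(g: SequenceGraph) -> list[int]:
    """DFS reverse postorder: a true topological order on acyclic graphs and
    a good processing heuristic on cyclic ones (back edges only within
    strongly connected components)."""
    n = g.node_count
    seen = [False] * n
    order: list[int] = []
    for root in range(n):
        if seen[root]:
            continue
        stack: list[tuple[int, int]] = [(root, 0)]
        seen[root] = True
        while stack:
            v, i = stack.pop()
            outs = g.out_edges[v]
            while i < len(outs) and seen[outs[i]]:
                i += 1
            if i < len(outs):
                stack.append((v, i + 1))
                w = outs[i]
                seen[w] = True
                stack.append((w, 0))
            else:
                order.append(v)
    order.reverse()
    return order


def normalize_singletons(g: SequenceGraph) -> SequenceGraph:
    """Merge degree-0 nodes sharing a label, so |V| <= 2|E| + |alphabet|."""
    keep: list[int] = []
    singleton_label_seen: dict[str, int] = {}
    remap: dict[int, int] = {}
    for i in range(g.node_count):
        if g.out_edges[i] or g.in_edges[i]:
            remap[i] = len(keep)
            keep.append(i)
        else:
            if g.labels[i] not in singleton_label_seen:
                singleton_label_seen[g.labels[i]] = len(keep)
                keep.append(i)
            remap[i] = singleton_label_seen[g.labels[i]]
    out = SequenceGraph()
    for i in keep:
        out.add_node(g.labels[i])
    for u in range(g.node_count):
        for v in g.out_edges[u]:
            out.add_edge(remap[u], remap[v])
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def sample_path(g: SequenceGraph, length: int, seed: int = 0) -> PathSample:
    """Uniform random walk of ``length`` nodes (repeats allowed).

    Starts at a random node and follows random out-edges.  On a dead end the
    walk restarts with a derived seed, up to 100 attempts, then raises.
    """
    if g.node_count == 0:
        raise GraphError("empty graph")
    if length < 1:
        raise GraphError("length must be >= 1")
    for attempt in range(100):
        rng = random.Random(seed * 1000003 + attempt)
        nodes = [rng.randrange(g.node_count)]
        while len(nodes) < length:
            outs = g.out_edges[nodes[-1]]
            if not outs:
                break
            nodes.append(rng.choice(outs))
        if len(nodes) == length:
            return PathSample(nodes, "".join(g.labels[v] for v in nodes))
    raise GraphError(f"no path of length {length} found after 100 attempts")


def mutate_sequence(
    seq: str,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    seed: int = 0,
) -> tuple[str, int]:
    """Apply i.i.d. per-position edits; returns ``(mutated, n_edits)``.

    Each position independently suffers a substitution (to a different base),
    an insertion of a random base after it, or a deletion.  The true edit
    distance to the original is at most ``n_edits``.
    """
    for r in (sub_rate, ins_rate, del_rate):
        if not 0 <= r <= 1:
            raise GraphError("rates must be in [0,1]")
    if sub_rate + ins_rate + del_rate > 1:
        raise GraphError("rates sum must be <= 1")
    rng = random.Random(seed)
    out: list[str] = []
    edits = 0
    for c in seq:
        u = rng.random()
        if u < sub_rate:
            out.append(rng.choice([b for b in DNA if b != c]))
            edits += 1
        elif u < sub_rate + ins_rate:
            out.append(c)
            out.append(rng.choice(DNA))
            edits += 1
        elif u < sub_rate + ins_rate + del_rate:
            edits += 1  # deleted
        else:
            out.append(c)
    return "".join(out), edits


def random_sequence(length: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(DNA) for _ in range(length))
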