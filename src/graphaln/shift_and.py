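"""Exact sequence-to-graph matching via a generalized Shift-And algorithm.

The classic Shift-And algorithm simulates an NFA matching the pattern: after
consuming a text character, bit ``i`` of the state is set iff the pattern
prefix of length ``i+1`` matches a suffix of the consumed text.  On a graph
the "text" is any path, so every node keeps its own state vector and the
invariant becomes: bit ``i`` of ``S[v]`` is set iff some path of length
``i+1`` ending at ``v`` spells ``s[0:i+1]``.

On DAGs one pass in topological order suffices, OR-merging the propagated
states of all in-neighbors.  On cyclic graphs a worklist iterates to the
fixed point; bits are only ever set, never cleared, so each node re-enters
the worklist at most ``m`` times and total work is O(|V| + m|E|) word steps.

State vectors are stored as tuples of ``word_size``-bit little-endian words
(``ceil(m / word_size)`` of them) and the shift step carries across words
explicitly, so the machinery matches what a C implementation on w-bit
registers would do.  ``word_size`` is configurable to stress multi-word
carries at small widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .graph import DNA_N, SequenceGraph, topological_order

Words = tuple[int, ...]


@dataclass(frozen=True)
class PatternMasks:
    """Per-character pattern bitmasks: bit i of ``masks[c]`` set iff s[i] == c.

    The masks partition the pattern positions: OR over all characters is the
    all-ones m-bit vector and distinct masks are disjoint.
    """

    pattern: str
    word_size: int
    masks: dict[str, Words]

    @property
    def m(self) -> int:
        return len(self.pattern)

    @property
    def n_words(self) -> int:
        return (self.m + self.word_size - 1) // self.word_size

    def mask_for(self, label: str) -> Words:
        """Mask for a node label; labels absent from the alphabet (e.g. 'N'
        under the lenient policy) match nothing."""
        return self.masks.get(label, (0,) * self.n_words)


def precompute_pattern_masks(
    s: str, alphabet: str = DNA_N, word_size: int = 64
) -> PatternMasks:
    if not s:
        raise ValueError("empty pattern")
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    for c in s:
        if c not in alphabet:
            raise ValueError(f"pattern character {c!r} outside alphabet {alphabet!r}")
    m = len(s)
    n_words = (m + word_size - 1) // word_size
    ints = {c: 0 for c in alphabet}
    for i, c in enumerate(s):
        ints[c] |= 1 << i
    masks = {c: int_to_words(v, n_words, word_size) for c, v in ints.items()}
    return PatternMasks(pattern=s, word_size=word_size, masks=masks)


def int_to_words(value: int, n_words: int, word_size: int) -> Words:
    wmask = (1 << word_size) - 1
    return tuple((value >> (i * word_size)) & wmask for i in range(n_words))


def words_to_int(words: Words, word_size: int) -> int:
    out = 0
    for i, w in enumerate(words):
        out |= w << (i * word_size)
    return out


def nfa_step(state: Words, mask: Words, word_size: int, m: int) -> Words:
    """One NFA transition: ``((state << 1) + 1) & mask``.

    The +1 seeds a fresh match start at every step; the shift advances all
    running matches; the AND keeps those whose next pattern character equals
    the consumed label.  The shift carry propagates across words explicitly,
    and bits beyond ``m`` are truncated.
    """
    wmask = (1 << word_size) - 1
    carry = 1  # the +1 term is the carry into the lowest word
    out = []
    for w in zip(state, mask):
        shifted = ((w[0] << 1) | carry) & wmask
        carry = w[0] >> (word_size - 1)
        out.append(shifted & w[1])
    # truncate bits >= m in the top word
    top_bits = m - (len(out) - 1) * word_size
    out[-1] &= (1 << top_bits) - 1
    return tuple(out)


def _or_words(a: Words, b: Words) -> Words:
    return tuple(x | y for x, y in zip(a, b))


@dataclass
class NfaStates:
    """Per-node NFA state vectors after running Shift-And to the fixed point."""

    masks: PatternMasks
    states: list[Words]

    def as_int(self, v: int) -> int:
        return words_to_int(self.states[v], self.masks.word_size)

    def bit(self, v: int, i: int) -> bool:
        return bool(self.as_int(v) >> i & 1)

    def match_nodes(self) -> list[int]:
        """Nodes where the full-match bit (m-1) is set: some path ending
        there spells the whole pattern."""
        full = self.masks.m - 1
        return [v for v in range(len(self.states)) if self.bit(v, full)]


def _initial_states(g: SequenceGraph, pm: PatternMasks) -> list[Words]:
    """Every node starts from the zero-predecessor step, which seeds bit 0
    where the node label equals s[0] (a match may start at any node; this
    also covers in-degree-0 nodes which no edge update ever reaches)."""
    zero = (0,) * pm.n_words
    return [nfa_step(zero, pm.mask_for(g.labels[v]), pm.word_size, pm.m) for v in range(g.node_count)]


def shift_and_dag(g: SequenceGraph, s: str, word_size: int = 64) -> NfaStates:
    """Single-pass Shift-And over a DAG in topological order."""
    order = topological_order(g)
    if order is None:
        raise ValueError("graph is cyclic; use shift_and_cyclic")
    pm = precompute_pattern_masks(s, word_size=word_size)
    states = _initial_states(g, pm)
    for v in order:
        sv = states[v]
        for y in g.out_edges[v]:
            states[y] = _or_words(states[y], nfa_step(sv, pm.mask_for(g.labels[y]), pm.word_size, pm.m))
    return NfaStates(pm, states)


def shift_and_cyclic(
    g: SequenceGraph, s: str, word_size: int = 64, debug_monotone: bool = False
) -> NfaStates:
    """Worklist Shift-And for arbitrary graphs.

    All nodes enter a LIFO worklist; popping a node propagates its state to
    its out-neighbors, re-pushing any neighbor whose state gained bits.
    States grow monotonically under bitwise inclusion, so the fixed point is
    reached after at most m pushes per node.  The fixed point is independent
    of the worklist order.
    """
    pm = precompute_pattern_masks(s, word_size=word_size)
    states = _initial_states(g, pm)
    work = list(range(g.node_count))
    in_list = [True] * g.node_count
    pops = [0] * g.node_count
    while work:
        v = work.pop()
        in_list[v] = False
        pops[v] += 1
        assert pops[v] <= pm.m + 1, "termination bound exceeded"
        sv = states[v]
        for y in g.out_edges[v]:
            old = states[y]
            new = _or_words(old, nfa_step(sv, pm.mask_for(g.labels[y]), pm.word_size, pm.m))
            if new != old:
                if debug_monotone:
                    assert words_to_int(new, word_size) & words_to_int(old, word_size) == words_to_int(old, word_size)
                states[y] = new
                if not in_list[y]:
                    work.append(y)
                    in_list[y] = True
    return NfaStates(pm, states)


@dataclass
class MatchResult:
    """Exact-match endpoints with witness paths."""

    end_nodes: list[int]
    paths: list[list[int]]
    truncated: bool = False


def extract_matches(
    states: NfaStates,
    g: SequenceGraph,
    s: str,
    max_paths: Optional[int] = None,
    enumerate_all: bool = False,
) -> MatchResult:
    """Recover match paths from converged NFA states.

    For each node with the full-match bit set, walk backwards: a predecessor
    ``u`` of the current node at prefix length ``i+1`` qualifies if bit
    ``i-1`` is set in ``S[u]`` (the states' exactness guarantees one exists).
    Default: one witness per end node; ``enumerate_all`` lists every distinct
    match path, truncated at ``max_paths`` (default cap 1000) with a flag.
    """
    m = len(s)
    cap = max_paths if max_paths is not None else 1000
    ends = states.match_nodes()
    paths: list[list[int]] = []
    truncated = False

    def backtrack(v: int, i: int, suffix: list[int], all_paths: bool) -> Iterator[list[int]]:
        if i == 0:
            yield [v] + suffix
            return
        for u in sorted(g.in_edges[v]):
            if states.bit(u, i - 1):
                yield from backtrack(u, i - 1, [v] + suffix, all_paths)
                if not all_paths:
                    return

    for v in ends:
        for p in backtrack(v, m - 1, [], enumerate_all):
            if len(paths) >= cap:
                truncated = True
                break
            paths.append(p)
        if truncated:
            break
    return MatchResult(end_nodes=ends, paths=paths, truncated=truncated)
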