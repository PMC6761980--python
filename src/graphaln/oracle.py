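"""Independent reference solvers for sequence-to-graph problems.

These are deliberately transparent implementations kept free of bit tricks:

* :func:`dijkstra_align` solves the semi-global alignment recurrence as a
  shortest-path problem on the edit graph (nonnegative unit costs, hence
  correct on cyclic graphs).
* :func:`cellwise_align` is the classic cell-by-cell algorithm that sweeps
  each row twice: diagonal+vertical terms first, then horizontal terms
  propagated depth-first to a fixed point.  It doubles as the runtime
  baseline the bit-parallel aligner is compared against.
* :func:`naive_exact_match` is a boolean reachability search used to verify
  the Shift-And NFA states.

The alignment score ``C[i][j]`` is the value of the recurrence

    C[i][j] = min( C[k][j-1] + delta(i,j)   for k in in(i),   # diagonal
                   C[k][j]   + 1            for k in in(i),   # horizontal
                   C[i][j-1] + 1 )                            # vertical

with boundary row ``C[i][0] = delta(i,0)`` (0-based rows; the query may start
at any node for free, and ends anywhere: the result is the minimum bottom-row
value).  Here ``delta(i,j)`` is 0 when node i's label equals query character
j, else 1.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from .graph import SequenceGraph

_CELL_GUARD = 10**7  # refuse |V| * m beyond this (transparency over scale)


@dataclass
class DpMatrix:
    """Full integer DP grid: ``values[i][j]`` for node i, query row j."""

    values: list[list[int]]  # |V| x m

    @property
    def best(self) -> int:
        return min(col[-1] for col in self.values)

    def argmin_end(self) -> int:
        """Node id with the smallest bottom-row score (lowest id on ties)."""
        best, node = None, -1
        for i, col in enumerate(self.values):
            if best is None or col[-1] < best:
                best, node = col[-1], i
        return node


def _delta(g: SequenceGraph, s: str):
    return lambda i, j: 0 if g.labels[i] == s[j] else 1


def _guard(g: SequenceGraph, s: str) -> None:
    if not s:
        raise ValueError("empty query")
    if g.node_count == 0:
        raise ValueError("empty graph")
    if g.node_count * len(s) > _CELL_GUARD:
        raise MemoryError(
            f"oracle refuses {g.node_count} x {len(s)} = "
            f"{g.node_count * len(s)} cells (> {_CELL_GUARD})"
        )


def dijkstra_align(g: SequenceGraph, s: str) -> DpMatrix:
    """Solve the alignment recurrence by Dijkstra on the edit graph.

    States are cells (node i, row j); a virtual source feeds every (i, 0)
    with cost delta(i,0); diagonal edges cost delta, horizontal and vertical
    edges cost 1.  All costs are nonnegative, so distances equal the unique
    recurrence solution on arbitrary (cyclic) graphs.
    """
    _guard(g, s)
    n, m = g.node_count, len(s)
    delta = _delta(g, s)
    INF = m + 1  # scores never exceed m
    dist = [[INF] * m for _ in range(n)]
    heap: list[tuple[int, int, int]] = []
    for i in range(n):
        d = delta(i, 0)
        dist[i][0] = d
        heap.append((d, i, 0))
    heapq.heapify(heap)
    while heap:
        d, i, j = heapq.heappop(heap)
        if d > dist[i][j]:
            continue
        # relax outgoing edit-graph edges
        if j + 1 < m:
            if d + 1 < dist[i][j + 1]:  # vertical
                dist[i][j + 1] = d + 1
                heapq.heappush(heap, (d + 1, i, j + 1))
        for y in g.out_edges[i]:
            if d + 1 < dist[y][j]:  # horizontal
                dist[y][j] = d + 1
                heapq.heappush(heap, (d + 1, y, j))
            if j + 1 < m:
                nd = d + delta(y, j + 1)  # diagonal
                if nd < dist[y][j + 1]:
                    dist[y][j + 1] = nd
                    heapq.heappush(heap, (nd, y, j + 1))
    return DpMatrix(dist)


def cellwise_align(g: SequenceGraph, s: str) -> DpMatrix:
    """Row-wise cell-by-cell evaluation with two sweeps per row.

    Sweep 1 applies the diagonal and vertical terms from the previous row;
    sweep 2 propagates the horizontal term along same-row edges depth-first,
    relaxing a cell only on strict improvement (termination on cycles).
    """
    _guard(g, s)
    n, m = g.node_count, len(s)
    delta = _delta(g, s)
    C = [[0] * m for _ in range(n)]

    for j in range(m):
        # sweep 1: diagonal + vertical (previous row; virtual zero row above row 0)
        for i in range(n):
            if j == 0:
                best = delta(i, 0)
            else:
                best = C[i][j - 1] + 1
                dj = delta(i, j)
                for k in g.in_edges[i]:
                    cand = C[k][j - 1] + dj
                    if cand < best:
                        best = cand
            C[i][j] = best
        # sweep 2: horizontal propagation, depth-first, strict improvements only
        stack = list(range(n))
        while stack:
            k = stack.pop()
            base = C[k][j] + 1
            for y in g.out_edges[k]:
                if base < C[y][j]:
                    C[y][j] = base
                    stack.append(y)
    return DpMatrix(C)


def audit_recurrence(g: SequenceGraph, s: str, mat: DpMatrix) -> None:
    """Raise AssertionError unless every cell satisfies the recurrence with
    equality and the vertical property holds."""
    n, m = g.node_count, len(s)
    delta = _delta(g, s)
    C = mat.values
    for i in range(n):
        for j in range(m):
            cands = []
            if j == 0:
                cands.append(delta(i, 0))
            else:
                cands.append(C[i][j - 1] + 1)
                for k in g.in_edges[i]:
                    cands.append(C[k][j - 1] + delta(i, j))
            for k in g.in_edges[i]:
                cands.append(C[k][j] + 1)
            assert C[i][j] == min(cands), f"cell ({i},{j}): {C[i][j]} != {min(cands)}"
            if j > 0:
                assert C[i][j] - C[i][j - 1] in (-1, 0, 1), f"vertical property at ({i},{j})"


def naive_exact_match(g: SequenceGraph, s: str) -> set[tuple[int, int]]:
    """All (node, prefix length L) pairs such that some length-L path ending
    at the node spells ``s[0:L]``.  Boolean BFS over (node, L) states."""
    if not s:
        raise ValueError("empty pattern")
    m = len(s)
    reached: set[tuple[int, int]] = set()
    frontier: list[tuple[int, int]] = []
    for v in range(g.node_count):
        if g.labels[v] == s[0]:
            reached.add((v, 1))
            frontier.append((v, 1))
    while frontier:
        v, L = frontier.pop()
        if L == m:
            continue
        for y in g.out_edges[v]:
            if g.labels[y] == s[L] and (y, L + 1) not in reached:
                reached.add((y, L + 1))
                frontier.append((y, L + 1))
    return reached


def semiglobal_dp(text: str, query: str) -> int:
    """Textbook semi-global sequence-to-sequence edit distance (free start
    and end in ``text``); oracle for linear-graph alignment."""
    m = len(query)
    # column-wise DP over text with free start: one column per text position
    prev_col = [0 if text[0] == query[0] else 1]
    for j in range(1, m):
        prev_col.append(prev_col[j - 1] + 1)
    best_bottom = prev_col[-1]
    for i in range(1, len(text)):
        cur = [0 if text[i] == query[0] else 1]
        cur[0] = min(cur[0], prev_col[0] + 1)
        for j in range(1, m):
            d = 0 if text[i] == query[j] else 1
            cur.append(min(prev_col[j - 1] + d, prev_col[j] + 1, cur[j - 1] + 1))
        prev_col = cur
        best_bottom = min(best_bottom, cur[-1])
    return best_bottom
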