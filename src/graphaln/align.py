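"""Semi-global sequence-to-graph alignment with bit-parallel columns.

The DP matrix has one column per graph node and one row per query character;
cell (i, j) is the recurrence value: the best unit-cost alignment of the
length-(j+1) query prefix against some path ending at node i, entering the
graph at row 0 (free choice of start node; the alignment ends at any node,
so the result is the minimum bottom-row score).

Engines
-------
* DAG: one pass per slice in topological order; each node merges the
  columns propagated over all in-edges (O(|V| + ceil(m/w) |E| log w)).
* Cyclic: a worklist with a bucket priority queue keyed by the minimum
  changed score; columns are recalculated until convergence, each node
  re-entering the queue at most once per converged cell (O(|V| + m |E| log w)).
* Sliced: the DP matrix is cut into bands of w rows processed top to bottom,
  each band running one of the engines above with per-node carry-over scores
  (``s_before``) from the band above.

Columns are initialized per slice to the pure vertical continuation of their
carry-over score; in the top slice that continuation starts from the virtual
all-zero row, i.e. the boundary column delta_0, delta_0+1, ... -- this also
makes in-degree-0 nodes (which no edge update ever reaches) exact from the
start.  Every per-edge update is a Myers block step followed by an
elementwise-minimum merge, so present scores decrease monotonically toward
the unique recurrence solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .bucketqueue import BucketQueue
from .columns import (
    INF,
    BitColumn,
    ColumnError,
    changed_min_bruteforce,
    decode_scores,
    merge_reference,
    merge_with_changed_min,
    myers_step,
)
from .graph import (
    CyclicGraphError,
    SequenceGraph,
    pseudo_topological_order,
    topological_order,
)


@dataclass
class SliceStats:
    """Convergence diagnostics for one slice."""

    pops: list[int]  # per node
    backward_moves: int = 0

    @property
    def max_pops(self) -> int:
        return max(self.pops) if self.pops else 0


@dataclass
class AlignmentColumns:
    """Converged columns of all slices plus the semi-global optimum."""

    graph: SequenceGraph
    query: str
    word_size: Optional[int]
    slices: list[list[BitColumn]]  # [slice][node]
    slice_bounds: list[tuple[int, int]]  # row ranges [lo, hi)
    best_score: int
    best_node: int
    stats: list[SliceStats]

    def decode_column(self, v: int) -> list[int]:
        out: list[int] = []
        for t in range(len(self.slices)):
            out.extend(decode_scores(self.slices[t][v]))
        return out

    def decode_matrix(self) -> list[list[int]]:
        return [self.decode_column(v) for v in range(self.graph.node_count)]


def _char_masks(s: str) -> dict[str, int]:
    masks: dict[str, int] = {}
    for i, c in enumerate(s):
        masks[c] = masks.get(c, 0) | 1 << i
    return masks


def _slice_bounds(m: int, w: Optional[int]) -> list[tuple[int, int]]:
    if w is None or w >= m:
        return [(0, m)]
    if w < 1:
        raise ValueError("word size must be >= 1")
    return [(lo, min(m, lo + w)) for lo in range(0, m, w)]


def _init_column(label_matches_row0: bool, top: bool, sb: int, k: int) -> BitColumn:
    ones = (1 << k) - 1
    if top and label_matches_row0:
        vp = ones & ~1  # boundary column with a row-0 match: 0, 1, 2, ...
    else:
        vp = ones
    return BitColumn(vp=vp, vn=0, s_before=sb, s_end=sb + vp.bit_count(), k=k)


def _rebase(col: BitColumn, sb: int) -> BitColumn:
    """Re-anchor a column to baseline ``sb`` keeping absolute row scores."""
    if col.s_before == sb:
        return col
    row0 = col.s_before + (col.vp & 1) - (col.vn & 1)
    step = row0 - sb
    if step not in (-1, 0, 1):
        raise ColumnError(f"cannot rebase: boundary step {step}")
    vp = (col.vp & ~1) | (1 if step == 1 else 0)
    vn = (col.vn & ~1) | (1 if step == -1 else 0)
    return BitColumn(vp=vp, vn=vn, s_before=sb, s_end=col.s_end, k=col.k)


def _clamp(x: int) -> int:
    return -1 if x < -1 else (1 if x > 1 else x)


class AlignmentEngine:
    """Shared slice machinery for the DAG and cyclic engines."""

    def __init__(
        self,
        g: SequenceGraph,
        s: str,
        word_size: Optional[int],
        crosscheck_merge: bool = False,
    ):
        if not s:
            raise ValueError("empty query")
        if g.node_count == 0:
            raise ValueError("empty graph")
        self.g = g
        self.s = s
        self.m = len(s)
        self.word_size = word_size
        self.masks = _char_masks(s)
        self.bounds = _slice_bounds(self.m, word_size)
        self.crosscheck_merge = crosscheck_merge
        self.seed_order = pseudo_topological_order(g)

    def _slice_masks(self, lo: int, k: int) -> list[int]:
        ones = (1 << k) - 1
        return [
            (self.masks.get(self.g.labels[v], 0) >> lo) & ones
            for v in range(self.g.node_count)
        ]

    def _edge_update(
        self,
        cols: list[BitColumn],
        sb: list[int],
        eq: list[int],
        v: int,
        y: int,
        touched: list[bool],
        top: bool,
        want_cm: bool = True,
    ) -> tuple[BitColumn, float]:
        """Propagate v's column over edge (v, y).

        Returns the merged column (re-anchored to y's carry-over score) and
        the minimum changed score of the update; the returned column is the
        identical ``cols[y]`` object when nothing can change.

        Fast path: while y still holds its untouched initialization column
        (the pure vertical continuation of its carry-over score) and the
        carry-over gap is not deeply negative, the freshly calculated
        candidate is dominated by it row for row, so the merge is the
        candidate itself and the changed rows form a suffix starting at the
        candidate's first non-+1 step.
        """
        hin = _clamp(sb[y] - sb[v])
        cand = myers_step(cols[v], eq[y], hin)
        old = cols[y]
        k = cand.k
        ones = (1 << k) - 1
        if (
            not touched[y]
            and sb[y] - sb[v] >= -1
            and not (top and eq[y] & 1)  # boundary init with a row-0 match
        ):
            t = sb[y] - cand.s_before
            vp, vn = cand.vp, cand.vn
            if t == 0 and vp == ones:
                return old, INF  # candidate equals the init column
            touched[y] = True
            merged = _rebase(cand, sb[y])
            if not want_cm:
                return merged, 0
            if t == 0:
                j0 = (~vp & (vp + 1)).bit_length() - 1  # first non-+1 step
                candmask = (~vp & ~(vn >> 1) & ones & ~((1 << j0) - 1)) | (1 << j0)
            else:  # init sits strictly above the candidate everywhere
                candmask = (~vp & ~(vn >> 1) & ones) | 1
            best = None
            c = candmask
            while c:
                j = (c & -c).bit_length() - 1
                c &= c - 1
                prefix = (1 << (j + 1)) - 1
                sc = (
                    cand.s_before
                    + (vp & prefix).bit_count()
                    - (vn & prefix).bit_count()
                )
                if best is None or sc < best:
                    best = sc
            return merged, best
        merged, cm = merge_with_changed_min(old, cand, want_changed_min=want_cm)
        if self.crosscheck_merge:
            ref = merge_reference(old, cand)
            if decode_scores(ref) != decode_scores(merged):
                raise AssertionError("merge crosscheck failed")
            if want_cm and cm != changed_min_bruteforce(old, merged):
                raise AssertionError("changed_min crosscheck failed")
        touched[y] = True
        return _rebase(merged, sb[y]), cm

    def run(self, use_queue: bool) -> AlignmentColumns:
        g, m = self.g, self.m
        n = g.node_count
        order: Optional[list[int]] = None
        if not use_queue:
            order = topological_order(g)
            if order is None:
                raise CyclicGraphError("graph is cyclic; use the cyclic engine")
        sb = [0] * n
        all_slices: list[list[BitColumn]] = []
        stats: list[SliceStats] = []
        for lo, hi in self.bounds:
            k = hi - lo
            eq = self._slice_masks(lo, k)
            cols = [
                _init_column(bool(eq[v] & 1), lo == 0, sb[v], k) for v in range(n)
            ]
            if use_queue:
                st = self._run_slice_queue(cols, sb, eq, k, top=lo == 0)
            else:
                st = self._run_slice_topo(cols, sb, eq, order, top=lo == 0)
            all_slices.append(cols)
            stats.append(st)
            sb = [c.s_end for c in cols]
        best_node = min(range(n), key=lambda v: (sb[v], v))
        return AlignmentColumns(
            graph=g,
            query=self.s,
            word_size=self.word_size,
            slices=all_slices,
            slice_bounds=self.bounds,
            best_score=sb[best_node],
            best_node=best_node,
            stats=stats,
        )

    def _run_slice_topo(
        self,
        cols: list[BitColumn],
        sb: list[int],
        eq: list[int],
        order: list[int],
        top: bool,
    ) -> SliceStats:
        g = self.g
        pops = [1] * g.node_count
        touched = [False] * g.node_count
        for v in order:
            for y in g.out_edges[v]:
                merged, _ = self._edge_update(
                    cols, sb, eq, v, y, touched, top, want_cm=False
                )
                cols[y] = merged
        return SliceStats(pops=pops)

    def _run_slice_queue(
        self,
        cols: list[BitColumn],
        sb: list[int],
        eq: list[int],
        k: int,
        top: bool,
    ) -> SliceStats:
        g, m = self.g, self.m
        n = g.node_count
        touched = [False] * n
        queue = BucketQueue(max_priority=m + 1, n_nodes=n)
        # seed so the initial pops follow a pseudo-topological order: the
        # first sweep is then a near-DAG pass and recalculation is confined
        # to cyclic regions (the fixed point is order-independent)
        for v in reversed(self.seed_order):
            queue.push(0, v)
        pops = [0] * n
        while len(queue):
            _, v = queue.pop()
            pops[v] += 1
            if pops[v] > k + 1:
                raise AssertionError(
                    f"node {v} popped {pops[v]} times in a {k}-row slice"
                )
            for y in g.out_edges[v]:
                # while y still waits in the queue at priority 0 any push is
                # a no-op, so the changed-minimum value is not needed
                need_cm = queue.priority[y] != 0
                merged, cm = self._edge_update(
                    cols, sb, eq, v, y, touched, top, want_cm=need_cm
                )
                if not need_cm:
                    cols[y] = merged
                elif cm != INF:
                    cols[y] = merged
                    queue.push(int(cm), y)
        return SliceStats(pops=pops, backward_moves=queue.backward_moves)


def align_dag(
    g: SequenceGraph,
    s: str,
    word_size: Optional[int] = None,
    crosscheck_merge: bool = False,
) -> AlignmentColumns:
    """Single-pass alignment for acyclic graphs (whole-column by default;
    pass ``word_size`` to slice)."""
    return AlignmentEngine(g, s, word_size, crosscheck_merge=crosscheck_merge).run(
        use_queue=False
    )


def align_cyclic(
    g: SequenceGraph,
    s: str,
    word_size: Optional[int] = None,
    crosscheck_merge: bool = False,
) -> AlignmentColumns:
    """Worklist alignment for arbitrary graphs (whole-column by default)."""
    return AlignmentEngine(g, s, word_size, crosscheck_merge=crosscheck_merge).run(
        use_queue=True
    )


def align_sliced(
    g: SequenceGraph,
    s: str,
    word_size: int = 64,
    crosscheck_merge: bool = False,
) -> AlignmentColumns:
    """Slice-by-slice driver: bands of ``word_size`` rows, the DAG engine on
    acyclic inputs and the worklist engine otherwise."""
    engine = AlignmentEngine(g, s, word_size, crosscheck_merge=crosscheck_merge)
    return engine.run(use_queue=topological_order(g) is None)


# ---------------------------------------------------------------------------
# Traceback
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    """A reported alignment: path, edit distance and per-base operations.

    ``operations`` uses '=' (match), 'X' (mismatch), 'I' (query character
    inserted relative to the path) and 'D' (path character not consumed by
    the query); its non-'=' count equals ``edit_distance``.
    """

    query_id: str
    query_length: int
    edit_distance: int
    path: list[int]
    operations: str
    end_node: int
    max_pops_per_slice: list[int] = field(default_factory=list)

    def cigar(self) -> str:
        if not self.operations:
            return ""
        out = []
        run, prev = 0, self.operations[0]
        for op in self.operations:
            if op == prev:
                run += 1
            else:
                out.append(f"{run}{prev}")
                run, prev = 1, op
        out.append(f"{run}{prev}")
        return "".join(out)

    @property
    def matches(self) -> int:
        return self.operations.count("=")


def traceback(cols: AlignmentColumns, query_id: str = "query") -> AlignmentResult:
    """Reconstruct one optimal alignment from converged columns.

    Starting at a bottom-row argmin cell, repeatedly move to a predecessor
    cell realizing the recurrence minimum, preferring diagonal over
    horizontal over vertical moves and smaller node ids among in-neighbors
    (deterministic output).  Stops at the row-0 boundary.
    """
    g, s = cols.graph, cols.query
    m = len(s)
    cache: dict[int, list[int]] = {}

    def col(v: int) -> list[int]:
        if v not in cache:
            cache[v] = cols.decode_column(v)
        return cache[v]

    def delta(i: int, j: int) -> int:
        return 0 if g.labels[i] == s[j] else 1

    i = cols.best_node
    j = m - 1
    ops: list[str] = []
    path: list[int] = []
    while True:
        c = col(i)[j]
        if j == 0:
            if c == delta(i, 0):  # entered the graph here
                path.append(i)
                ops.append("=" if delta(i, 0) == 0 else "X")
                break
            moved = False
            for p in sorted(g.in_edges[i]):
                if col(p)[0] + 1 == c:  # horizontal
                    path.append(i)
                    ops.append("D")
                    i = p
                    moved = True
                    break
            if not moved:
                raise AssertionError(f"no realizing predecessor at ({i},0)")
            continue
        moved = False
        d = delta(i, j)
        for p in sorted(g.in_edges[i]):  # diagonal
            if col(p)[j - 1] + d == c:
                path.append(i)
                ops.append("=" if d == 0 else "X")
                i, j = p, j - 1
                moved = True
                break
        if moved:
            continue
        for p in sorted(g.in_edges[i]):  # horizontal
            if col(p)[j] + 1 == c:
                path.append(i)
                ops.append("D")
                i = p
                moved = True
                break
        if moved:
            continue
        if col(i)[j - 1] + 1 == c:  # vertical
            ops.append("I")
            j -= 1
            continue
        raise AssertionError(f"no realizing predecessor at ({i},{j})")
    path.reverse()
    ops.reverse()
    return AlignmentResult(
        query_id=query_id,
        query_length=m,
        edit_distance=cols.best_score,
        path=path,
        operations="".join(ops),
        end_node=cols.best_node,
        max_pops_per_slice=[st.max_pops for st in cols.stats],
    )
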