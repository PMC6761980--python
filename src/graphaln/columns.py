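"""Bitvector representation of DP columns and the column operations.

A DP column (or a w-row slice of one) with the *vertical property* -- scores
of vertically adjacent cells differ by at most one -- is stored as

* ``vp``: bit j set iff score(row j) - score(row j-1) = +1,
* ``vn``: bit j set iff the difference is -1 (``vp & vn == 0``),
* ``s_before``: the score just above the column's top row (0 in whole-column
  mode, the previous slice's bottom score in sliced mode),
* ``s_end``: the score at the bottom row, kept redundantly for O(1) access.

Score at row j decodes to ``s_before + popcount(vp[0..j]) - popcount(vn[0..j])``.

The operations here are the building blocks of the graph aligner:

* :func:`myers_step` -- advance a column across one edge (the classic Myers /
  Hyyrö block step with a horizontal carry-in),
* :func:`merge_reference` / :func:`merge_bitparallel` -- elementwise minimum
  of two columns; the reference path decodes and re-encodes, the bit-parallel
  path runs in O(log k) elementary operations per machine word,
* :func:`changed_min` -- the minimum score among rows where a column strictly
  improved; the priority that drives convergence on cyclic graphs.

Bitvectors are Python integers; in sliced mode a column covers at most one
machine word of rows, and in whole-column mode the arbitrary-precision
arithmetic performs exactly the word-by-word carry propagation a fixed-width
implementation would spell out.
"""

from __future__ import annotations

import math
from typing import NamedTuple

INF = math.inf


class ColumnError(ValueError):
    pass


class BitColumn(NamedTuple):
    """One DP column slice in VP/VN bitvector form (k rows)."""

    vp: int
    vn: int
    s_before: int
    s_end: int
    k: int

    def validate(self) -> None:
        ones = (1 << self.k) - 1
        if self.vp & self.vn:
            raise ColumnError("vp and vn overlap")
        if self.vp & ~ones or self.vn & ~ones:
            raise ColumnError("bits beyond k")
        if self.s_end != self.s_before + self.vp.bit_count() - self.vn.bit_count():
            raise ColumnError("s_end inconsistent with vp/vn/s_before")


def decode_scores(col: BitColumn) -> list[int]:
    """Exact scores of all k rows (last equals ``s_end``)."""
    if col.vp & col.vn:
        raise ColumnError("vp and vn overlap")
    out = []
    s = col.s_before
    for j in range(col.k):
        s += (col.vp >> j & 1) - (col.vn >> j & 1)
        out.append(s)
    return out


def encode_scores(scores: list[int], s_before: int = 0) -> BitColumn:
    """Inverse of :func:`decode_scores`; rejects sequences violating the
    vertical property (adjacent steps outside {-1, 0, +1})."""
    vp = vn = 0
    prev = s_before
    for j, s in enumerate(scores):
        step = s - prev
        if step == 1:
            vp |= 1 << j
        elif step == -1:
            vn |= 1 << j
        elif step != 0:
            raise ColumnError(f"vertical property violated at row {j}: step {step}")
        prev = s
    return BitColumn(vp=vp, vn=vn, s_before=s_before, s_end=prev, k=len(scores))


# ---------------------------------------------------------------------------
# Myers / Hyyrö block step
# ---------------------------------------------------------------------------


def myers_step(pred: BitColumn, eq: int, hin: int = 0) -> BitColumn:
    """Calculate a column from a predecessor column across one edge.

    ``eq`` is the match mask for the destination node's label restricted to
    this slice's rows; ``hin`` is the horizontal score difference at the row
    just above the slice (output s_before minus input s_before), in
    {-1, 0, +1}.  The decoded output equals the alignment recurrence
    restricted to this single predecessor: with input scores I and output O,

        O[j] = min(I[j-1] + delta[j], I[j] + 1, O[j-1] + 1)

    where I[-1] = s_before(pred), O[-1] = I[-1] + hin and delta[j] = 0 iff
    eq bit j is set.
    """
    if hin not in (-1, 0, 1):
        raise ColumnError(f"hin must be in {{-1,0,1}}, got {hin}")
    k = pred.k
    ones = (1 << k) - 1
    vp, vn = pred.vp, pred.vn
    if hin < 0:
        eq |= 1
    eq &= ones
    xv = eq | vn
    xh = ((((eq & vp) + vp) & ones) ^ vp) | eq
    ph = vn | (~(xh | vp) & ones)
    mh = vp & xh
    ph = (ph << 1) & ones
    mh = (mh << 1) & ones
    if hin > 0:
        ph |= 1
    elif hin < 0:
        mh |= 1
    vp_out = (mh | (~(xv | ph) & ones)) & ones
    vn_out = ph & xv
    sb = pred.s_before + hin
    return BitColumn(
        vp=vp_out,
        vn=vn_out,
        s_before=sb,
        s_end=sb + vp_out.bit_count() - vn_out.bit_count(),
        k=k,
    )


# ---------------------------------------------------------------------------
# Column merging (elementwise minimum)
# ---------------------------------------------------------------------------


def merge_reference(a: BitColumn, b: BitColumn) -> BitColumn:
    """Decode -> elementwise min -> re-encode.  Authoritative but O(k)."""
    if a.k != b.k:
        raise ColumnError("width mismatch")
    sa, sb = decode_scores(a), decode_scores(b)
    merged = [min(x, y) for x, y in zip(sa, sb)]
    return encode_scores(merged, min(a.s_before, b.s_before))


def _chunk_width(k: int) -> int:
    # enough bits for a biased difference of two vertical-property columns:
    # |initial offset| clamped below 2k plus a +-2-per-row swing over k rows,
    # biased into [1, 2^c - 1]
    return (k - 1).bit_length() + 3 if k > 1 else 3


_MERGE_CONSTANTS: dict[int, tuple[int, int, int, int, int]] = {}


def _merge_constants(k: int) -> tuple[int, int, int, int, int]:
    """(c, nlanes, full, anchor, htop) for the chunked difference scan."""
    cached = _MERGE_CONSTANTS.get(k)
    if cached is None:
        c = _chunk_width(k)
        nlanes = -(-k // c)
        full = (1 << (nlanes * c)) - 1
        anchor = 0
        for t in range(nlanes):
            anchor |= 1 << (t * c)
        htop = anchor << (c - 1)
        cached = _MERGE_CONSTANTS[k] = (c, nlanes, full, anchor, htop)
    return cached


def _sign_masks(a: BitColumn, b: BitColumn) -> tuple[int, int]:
    """Row masks (gt, lt): bit j of gt set iff score_a[j] > score_b[j],
    bit j of lt iff score_a[j] < score_b[j].  O(log k) elementary ops."""
    k = a.k
    ones = (1 << k) - 1
    d0 = a.s_before - b.s_before
    if abs(d0) >= 2 * k:
        # the sign cannot flip within k rows; only the final row may reach 0
        d_end = a.s_end - b.s_end
        if d0 > 0:
            gt = ones if d_end != 0 else ones & ~(1 << (k - 1))
            return gt, 0
        lt = ones if d_end != 0 else ones & ~(1 << (k - 1))
        return 0, lt

    c, nlanes, full, anchor, htop = _merge_constants(k)
    bias = 1 << (c - 1)

    def lane_popcounts(x: int) -> int:
        acc = 0
        for i in range(c):
            acc += (x >> i) & anchor
        return acc

    # per-lane counts of rows strictly before each lane's anchor row
    p_inc = lane_popcounts(a.vp) + lane_popcounts(b.vn)
    n_inc = lane_popcounts(a.vn) + lane_popcounts(b.vp)
    sh = 1
    while sh < nlanes:
        p_inc = (p_inc + (p_inc << (sh * c))) & full
        n_inc = (n_inc + (n_inc << (sh * c))) & full
        sh <<= 1
    p_exc = (p_inc << c) & full
    n_exc = (n_inc << c) & full

    # biased difference at the row just above each lane's first row
    d = ((bias + d0) * anchor + p_exc - n_exc) & full
    gt = lt = 0
    for i in range(c):
        # advance every lane one row down (to row t*c + i)
        sub = ((a.vn >> i) & anchor) + ((b.vp >> i) & anchor)
        add = ((a.vp >> i) & anchor) + ((b.vn >> i) & anchor)
        d = (d - sub + add) & full
        # lane sign bits: value > bias / value < bias
        gt_lanes = d & ((d | htop) - anchor) & htop
        lt_lanes = ~d & htop
        gt |= ((gt_lanes >> (c - 1)) & anchor) << i
        lt |= ((lt_lanes >> (c - 1)) & anchor) << i
    return gt & ones, lt & ones


def merge_bitparallel(a: BitColumn, b: BitColumn) -> BitColumn:
    """Elementwise-minimum merge in O(log k) elementary operations.

    Chunked biased differences yield per-row sign masks of score_a - score_b;
    the output bits follow column B wherever the difference stays >= 0 across
    a row boundary, column A wherever it stays <= 0, and flatten to a 0-step
    at strict sign crossings (where min switches source mid-slope).
    Decodes identically to :func:`merge_reference`.
    """
    if a.k != b.k:
        raise ColumnError("width mismatch")
    k = a.k
    ones = (1 << k) - 1
    gt, lt = _sign_masks(a, b)
    d0 = a.s_before - b.s_before
    gt_prev = ((gt << 1) | (1 if d0 > 0 else 0)) & ones
    lt_prev = ((lt << 1) | (1 if d0 < 0 else 0)) & ones
    take_b = ~lt_prev & ~lt & ones  # difference >= 0 on both sides: min is B
    take_a = (~gt_prev & ~gt & ones) & ~take_b
    vp = (take_b & b.vp) | (take_a & a.vp)
    vn = (take_b & b.vn) | (take_a & a.vn)
    sb = min(a.s_before, b.s_before)
    return BitColumn(vp=vp, vn=vn, s_before=sb, s_end=sb + vp.bit_count() - vn.bit_count(), k=k)


# ---------------------------------------------------------------------------
# Changed minimum value
# ---------------------------------------------------------------------------


def changed_min_bruteforce(old: BitColumn, new: BitColumn) -> float:
    """Definition: min of new scores over rows where new < old, else +inf."""
    if old.k != new.k:
        raise ColumnError("width mismatch")
    so, sn = decode_scores(old), decode_scores(new)
    changed = [n for o, n in zip(so, sn) if n < o]
    return min(changed) if changed else INF


def changed_min(old: BitColumn, new: BitColumn) -> float:
    """Fast path: locate candidate rows by bit operations, then evaluate
    only those by popcount.

    The minimum over the changed-row mask is attained at a local minimum of
    the new column (no +1 step in, no -1 step out) or at a boundary row of a
    changed run, so only those rows are decoded.
    """
    if old.k != new.k:
        raise ColumnError("width mismatch")
    k = new.k
    ones = (1 << k) - 1
    changed, _ = _sign_masks(old, new)  # rows where old > new
    if changed == 0:
        return INF
    local_min = ~new.vp & ~(new.vn >> 1) & ones
    run_start = changed & ~((changed << 1) & ones)
    run_end = changed & ~(changed >> 1)
    cand = changed & (local_min | run_start | run_end)
    best = None
    c = cand
    while c:
        j = (c & -c).bit_length() - 1
        c &= c - 1
        prefix = (1 << (j + 1)) - 1
        s = new.s_before + (new.vp & prefix).bit_count() - (new.vn & prefix).bit_count()
        if best is None or s < best:
            best = s
    return best if best is not None else INF


def merge_with_changed_min(
    old: BitColumn, cand: BitColumn, want_changed_min: bool = True
) -> tuple[BitColumn, float]:
    """Fused engine path: merge ``old`` with a freshly calculated candidate
    column and report ``changedMin(old, merged)`` from the same difference
    scan.  Rows where the merged column strictly improves on ``old`` are
    exactly the rows where ``cand`` is smaller, so the merge's sign masks
    double as the changed-row mask."""
    if old.k != cand.k:
        raise ColumnError("width mismatch")
    k = old.k
    ones = (1 << k) - 1
    gt, lt = _sign_masks(old, cand)
    d0 = old.s_before - cand.s_before
    gt_prev = ((gt << 1) | (1 if d0 > 0 else 0)) & ones
    lt_prev = ((lt << 1) | (1 if d0 < 0 else 0)) & ones
    take_b = ~lt_prev & ~lt & ones
    take_a = (~gt_prev & ~gt & ones) & ~take_b
    vp = (take_b & cand.vp) | (take_a & old.vp)
    vn = (take_b & cand.vn) | (take_a & old.vn)
    sb = old.s_before if d0 <= 0 else cand.s_before
    merged = BitColumn(
        vp=vp, vn=vn, s_before=sb, s_end=sb + vp.bit_count() - vn.bit_count(), k=k
    )
    if not want_changed_min or gt == 0:
        return merged, INF
    local_min = ~vp & ~(vn >> 1) & ones
    run_start = gt & ~((gt << 1) & ones)
    run_end = gt & ~(gt >> 1)
    c = gt & (local_min | run_start | run_end)
    best = None
    while c:
        j = (c & -c).bit_length() - 1
        c &= c - 1
        prefix = (1 << (j + 1)) - 1
        s = sb + (vp & prefix).bit_count() - (vn & prefix).bit_count()
        if best is None or s < best:
            best = s
    return merged, best if best is not None else INF
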