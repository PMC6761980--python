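"""Monotone bucket priority queue with decrease-key semantics.

Priorities are DP scores, bounded by the query length m, so the queue is an
array of m+2 buckets plus a per-node current-priority table.  ``push(p, v)``
inserts v, lowers its priority if p is smaller, and ignores pushes at equal
or higher priority.  A scan pointer sweeps the buckets upward; a push below
the pointer moves it back (counted as a diagnostic -- convergence theory
suggests it cannot happen, which the counter lets us measure rather than
assume).  Amortized O(1) per operation; n mixed operations over |V| nodes
cost O(|V| + m + n).
"""

from __future__ import annotations

from typing import Optional


class BucketQueue:
    def __init__(self, max_priority: int, n_nodes: int):
        self.max_priority = max_priority
        self.buckets: list[list[int]] = [[] for _ in range(max_priority + 1)]
        self.priority: list[Optional[int]] = [None] * n_nodes
        self.ptr = 0
        self.size = 0
        self.backward_moves = 0  # pushes that landed below the scan pointer

    def __len__(self) -> int:
        return self.size

    def push(self, p: int, v: int) -> None:
        if not 0 <= p <= self.max_priority:
            raise ValueError(f"priority {p} out of range [0,{self.max_priority}]")
        cur = self.priority[v]
        if cur is not None and p >= cur:
            return  # equal or larger: do nothing
        if cur is None:
            self.size += 1
        self.priority[v] = p  # stale entry in old bucket skipped at pop
        self.buckets[p].append(v)
        if p < self.ptr:
            self.backward_moves += 1
            self.ptr = p

    def pop(self) -> tuple[int, int]:
        if self.size == 0:
            raise IndexError("pop from empty BucketQueue")
        while True:
            bucket = self.buckets[self.ptr]
            while bucket:
                v = bucket.pop()
                if self.priority[v] == self.ptr:
                    self.priority[v] = None
                    self.size -= 1
                    return self.ptr, v
            self.ptr += 1
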