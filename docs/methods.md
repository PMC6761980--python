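# Methods

## Model

A sequence graph is a directed graph `G = (V, E, σ)` with one character per
node over Σ = {A,C,G,T} (plus N under the lenient input policy; N matches
nothing, so it can only be aligned as an edit). Paths may repeat nodes, so
cyclic graphs denote infinite path languages. Two problems are solved:
exact matching (all paths spelling the query) and unit-cost semi-global
alignment (a path minimizing edit distance to the query, free path start
and end). Segment-based GFA 1.0 input is expanded one character per node;
`-` orientations materialize reverse-complement segment copies, and strand
handling is otherwise delegated to explicit reverse-complement doubling of
the whole graph, mirroring how read mappers treat bidirected graphs as two
mirrored strands. Node ids are dense 0-based integers and all row indices
are 0-based internally.

## The alignment recurrence and its boundary

The DP value `C[i][j]` satisfies the diagonal/horizontal/vertical
recurrence with boundary row `C[i][0] = Δ(i,0)`; the reported score is the
minimum bottom-row value. Despite cyclic dependencies the solution is
unique, because every cell's value is a shortest-path distance in the edit
graph (nonnegative arc costs): states `(i,j)`, a virtual source feeding
every `(i,0)` at cost `Δ(i,0)`, diagonal arcs costing `Δ`, horizontal and
vertical arcs costing 1. That shortest-path formulation is implemented
verbatim as `oracle.dijkstra_align` and is the correctness authority for
everything else.

One boundary subtlety is intentional and documented: the recurrence has no
"late entry" term, i.e. no alignment may begin with query-consuming
insertions *before* the path's first node. For any node with an in-neighbor
this costs nothing (the diagonal term from the neighbor dominates the
late-entry candidate), so the distinction only exists at in-degree-0 nodes:
a single node `G` scores 2 against query `AG`, although the unconstrained
edit distance d("G","AG") is 1. All solvers in this package — bit-parallel,
cell-by-cell, Dijkstra — share this convention, so they agree cell for
cell; the test suite's external edlib cross-check closes a linear chain
into a cycle (every node then has in-degree 1, walks = substrings of the
unrolled text) to make the comparison exact.

## Bitvector representation

A column slice of k rows stores `VP`/`VN` step bitvectors, the score
`S_before` just above its top row, and the bottom score `S_end`
(redundant, kept for O(1) access). Scores decode as `S_before` plus prefix
popcount differences. The vertical property (adjacent steps in {−1,0,+1})
is the representability precondition; `encode_scores` rejects violations,
so any vertical-property breach in the pipeline fails loudly rather than
silently corrupting scores. In sliced mode every slice is at most one
machine word; in whole-column mode Python's arbitrary-precision integers
carry across word boundaries exactly as an explicit multi-word loop would
(the Shift-And module keeps an explicit word-array implementation with
manual carries, exercised in tests at word size 8 to stress multi-word
paths).

## Column operations

**Myers step.** The standard block formulation with a horizontal carry-in
`hin ∈ {−1,0,+1}`: the output column equals the recurrence restricted to a
single predecessor column, verified against direct recurrence evaluation
on randomized columns (property tests) and used unchanged by both engines.

**Merge.** The elementwise minimum of two columns. The reference
implementation decodes, takes minima, re-encodes (the minimum of two
vertical-property sequences again has the vertical property). The
bit-parallel implementation computes per-row *sign masks* of the score
difference `S_A − S_B` by a chunked scan: the difference at each chunk
anchor row is built from SWAR per-chunk popcounts and a log-depth prefix
sum, then all chunks advance one row per iteration. Output bits follow
column B wherever the difference is ≥ 0 on both sides of a row boundary,
column A in the mirrored case, and flatten to a 0-step at strict sign
crossings; this reproduces the minimum's steps exactly, which the suite
verifies against the reference on tens of thousands of random pairs and
exhaustively at width 3.

*Chunk width.* Chunks use `⌊log2 k⌋ + 3` bits (k = slice height). The
difference of two vertical-property columns can swing ±2 per row on top of
the initial `S_before` offset, so biased lane values need the extra
headroom bit beyond the `log2 k + 2` one might first expect; the offset
itself is clamped to ±2k, which is sign-preserving because a difference
that large cannot change sign within k rows (offsets beyond that short-cut
to "one column dominates", with a single popcount fixing the possible tie
at the last row).

**Changed minimum.** `changedMin(old,new)` — the smallest new score among
strictly improved rows, +∞ if none — is the priority driving convergence.
The fast path derives the strictly-improved row mask from the same sign
machinery, then evaluates only candidate rows: local minima of the new
column (no +1 step in, no −1 step out) plus changed-run boundaries, each
by two popcounts. Equivalence with the brute-force definition is asserted
on the same random-pair corpus. Priorities are bounded by m, so +∞ is
represented as m+1 in the queue.

## Engines

Per slice, every column is initialized to the pure vertical continuation of
its carry-over score — in the top slice that continuation starts from the
virtual all-zero row, i.e. the boundary column `Δ₀, Δ₀+1, …`. This
initialization is an upper bound on the correct scores for every node and
is *exact* for in-degree-0 nodes, which no edge update ever reaches; it is
what makes sources correct in both engines.

The DAG engine performs one pass per slice in topological order, merging
each edge's stepped column into its destination. The cyclic engine seeds
all nodes at priority 0 into a bucket queue (m+2 buckets, per-node current
priority, decrease-key by re-insertion with stale-entry skipping) and
re-pushes a node whenever an update strictly improves some row, at the
changed-minimum priority. Scores decrease monotonically, each re-pop is
preceded by at least one cell converging, and the fixed point solves the
recurrence — asserted wholesale against the Dijkstra oracle.

Three engineering choices matter for speed without touching semantics:

* the queue is seeded in DFS reverse-postorder (a true topological order on
  acyclic inputs), so the first sweep is a near-DAG pass and recalculation
  is confined to cyclic regions — the fixed point is order-independent;
* while a destination node still waits in the queue at priority 0, a push
  is by definition a no-op, so the changed-minimum evaluation is skipped
  for it;
* while a destination still holds its untouched initialization column and
  the carry-over gap across the edge is ≥ −1, the freshly stepped candidate
  is dominated by that init column row for row, so the merge is the
  candidate itself and its changed rows form a suffix beginning at the
  candidate's first non-+1 step (the candidate's score-minus-row is
  non-increasing); this "pristine column" fast path handles the in-degree-1
  backbone of realistic graphs.

**Slice boundaries.** Slice t+1's `S_before` per node is slice t's
converged `S_end`. The horizontal carry-in for an edge (v→y) is
`S_before[y] − S_before[v]` clamped to {−1,0,+1}. Clamping from above
(+1 when the true gap is larger) cannot lose candidates: the spurious
vertical boundary term it introduces is dominated by the step's own
diagonal term. Clamping from below (−1 when the true gap is more negative)
can only make the candidate too *high*, and the lost slack is exactly the
vertical-continuation column the destination was initialized with, which
the merge restores; the candidate is afterwards re-anchored to the
destination's fixed `S_before` (an O(1) bit-0 adjustment, valid because
both its row-0 score and the correct one lie within ±1 of that anchor).
These claims are not taken on faith — the sliced engine at w=8 is asserted
bit-for-score identical to the whole-column engine and to the Dijkstra
oracle across the randomized corpus.

**Pop bound.** Algorithm theory bounds convergence pops: each re-pop is
preceded by a cell converging, giving ≤ k re-pops per node per k-row
slice. The initial seeding pop (every node enters the queue once at
priority 0) is not a convergence event, so total pops can reach k+1 at
small k; the invariant asserted throughout (tests, acceptance, and a hard
engine assertion at k+1) is the convergence-pop count. The queue also
counts scan-pointer backward moves rather than assuming they cannot occur;
the acceptance corpus observes zero.

**Traceback.** All slices' columns are retained (O(|V|·⌈m/w⌉) words); from
a bottom-row argmin cell the predecessor realizing the recurrence minimum
is re-identified by lazily decoding columns, preferring diagonal over
horizontal over vertical and the smallest in-neighbor id — a deterministic
tie-break so fixtures and GAF output are reproducible. Horizontal moves
strictly decrease the score, so the walk terminates on cyclic graphs. The
emitted operation string over {=,X,I,D} replays the query from the path
with exactly `edit distance` non-'=' operations (asserted).

## Exact matching

Pattern masks are stored as ⌈m/w⌉ explicit words; the NFA transition
`((S≪1)+1) AND P_c` propagates its shift carry across words manually. The
"+1" seeds a fresh match start at every step, which resolves the seeding of
bit 0: every node's state is initialized with the zero-predecessor step
(bit 0 iff its label equals s[0]), covering in-degree-0 nodes that edge
updates never reach — this is the exact fixed point, not merely a sound
approximation. The cyclic worklist is LIFO; the fixed point is
order-independent (bits are only ever set), and tests also run the DAG
variant against it. Full "all paths" output is exponential, so the default
reports match end-nodes with one witness path each (backward walk through
qualifying predecessors), with opt-in exhaustive enumeration capped at
1000 paths and a truncation flag.

## Reference solvers

`dijkstra_align` (above) and `cellwise_align`, the row-wise two-sweep
cell-by-cell algorithm: sweep one applies diagonal and vertical terms from
the previous row, sweep two propagates horizontal terms depth-first,
relaxing only on strict improvement (termination on cycles). The cellwise
solver is deliberately kept as a per-cell pure-Python evaluation — it is
the algorithmic baseline the bit-parallel engine is timed against, and
vectorizing it would change the comparison's subject from algorithms to
array libraries. Both oracles keep plain integer matrices, audit the
recurrence cell by cell in tests, and refuse instances beyond 10^7 cells.

## Synthetic data

The generators reproduce the benchmark topology families: a linear chain;
an SNP graph with Bernoulli(0.1) two-node bubbles (one SNP per 10 bp on
average; the reference node is kept and the alternative is wired to the
same neighbors); a twopath graph of two parallel chains with full cross
edges so every non-first node has in-degree 2 (the merge-heavy worst case;
second-chain labels random by default, duplicable on request); and a
tangle graph built from the k-mer de Bruijn graph of the input (default
k=11, chosen small so repeats induce cycles), with unitig compaction,
removal of the (k−1)-overlap by trimming every non-tip node's tail
(tips — out-degree 0 — keep their full string; unitigs emptied by trimming
are removed with neighbor reconnection, preserving walk labels, which an
exhaustive small-case enumeration against the uncompacted de Bruijn graph
verifies). Reverse-complement doubling is available for all of them.
Benchmark sequences are uniform random DNA; real genomes are more
repetitive, so a real tangle graph of equal size would be more cyclic than
the random one — the runtime comparison here therefore probes the
less favorable-to-cellwise end, and correctness claims are independent of
sequence composition. Simulated reads are random graph walks with i.i.d.
per-base substitutions/insertions/deletions (default 1–2% each in the
examples, long-read-like error structure without the bursty homopolymer
artifacts of real instruments); the reported edit count upper-bounds the
true distance, which tests assert.

## Problem sizes

Randomized corpora use graphs of ≤ 30 nodes with edge density up to 3|V|
and queries up to 40 characters — large enough to hit multi-slice, cyclic,
multi-in-degree and clamped-boundary paths simultaneously, small enough
that the Dijkstra oracle stays exact and fast; counts (600 alignment
instances, 200 matching instances, 10 000 merge pairs) follow the
package's acceptance policy. The runtime comparison uses a 10 kb doubled
tangle graph (~20 000 nodes) and 100 bp reads, where the bit-parallel
engine runs ~3–5× faster than the cell-by-cell baseline; the ratio is
reported, not asserted beyond its sign, since it is hardware- and
interpreter-dependent.

## Known limitations

Unit costs only: no affine gaps, no generalized integer costs, no banding
or seeding heuristics — the engines always fill the complete matrix.
Python-level bit-parallelism pays interpreter overhead per column
operation, so absolute throughput is far from a C implementation even
though the operation counts scale as advertised. GFA support is the 1.0
S/L dialect with 0M/* overlaps (P-lines ignored, no GFA 2.0); graphs with
nonzero segment overlaps must be preprocessed (the tangle generator does
its own overlap removal). The empty query is rejected rather than scored.
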