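# graphaln

Bit-parallel exact matching and semi-global alignment of sequencing reads to
**node-labeled sequence graphs** — variation graphs, de Bruijn / assembly
graphs, or any directed graph (cyclic included) where each node carries one
character and a path spells the concatenation of its labels.

Aligning reads to graphs is the core step of graph-based genome inference:
mapping to a pan-genome, anchoring long reads to an assembly graph for error
correction, or genotyping against a variation graph. The classic
cell-by-cell dynamic programs solve it in `O(|V| + m|E|)` time for a read of
length `m`; this package instead processes `w` dynamic-programming rows per
machine-word operation, the same bit-parallel idea that makes Myers'
algorithm the standard for sequence-to-sequence edit distance.

## Problems and algorithms

**Exact matching (SGM).** Find the paths `p` with `σ(p) = s`. The Shift-And
NFA simulation carries an `m`-bit state per node: bit `i` of `S[v]` is set
iff some path of length `i+1` ending at `v` spells `s[0..i]`. On a DAG one
pass in topological order suffices, OR-merging the shifted states of all
in-neighbors; on cyclic graphs a worklist iterates to the (monotone) fixed
point — `O(|V| + ⌈m/w⌉|E|)` and `O(|V| + m|E|)` word operations.

**Semi-global alignment (SGA).** Find a path minimizing the unit-cost edit
distance `d(σ(p), s)`, with free choice of path start and end. The DP matrix
has one column per node:

    C[i][j] = min( C[k][j-1] + Δ(i,j),   k ∈ in(i)    (diagonal)
                   C[k][j]   + 1,        k ∈ in(i)    (horizontal)
                   C[i][j-1] + 1 )                    (vertical)

with boundary row `C[i][0] = Δ(i,0)`. Vertically adjacent cells differ by at
most 1 (the *vertical property*), so a column is stored as Myers-style
`VP`/`VN` bitvectors plus scalar anchor scores. Three column operations
drive the solver:

* a **Myers block step** `F(column, P_c)` computing a successor column
  across one edge;
* a **bit-parallel merge** `⊗` taking the elementwise minimum of two
  columns in `O(log k)` word operations (chunked biased differences → sign
  masks → picking mask), needed wherever in-degree exceeds one;
* the **minimum changed score** `changedMin(old, new)`, the smallest score
  among strictly improved rows, located through local-minima bit masks.

Acyclic graphs take one merge-as-you-go pass per slice in topological
order. Cyclic graphs run a worklist keyed by the changed minimum in a
bucket priority queue; scores only decrease, every re-pop is paid for by a
newly converged cell, and the fixed point is the unique recurrence
solution — `O(|V| + ⌈m/w⌉|E| log w)` for DAGs, `O(|V| + m|E| log w)` in
general, with the matrix processed in `w`-row slices top to bottom.

Both algorithms are cross-checked in the test suite against independent
oracles: Dijkstra on the edit graph, the two-sweep cell-by-cell solver, a
boolean reachability BFS, and (via a circular chain) edlib.

## Worked example

Generate a 60 bp SNP graph (a linear chain with ~1 bubble per 10 bp, 68
nodes / 75 edges), simulate two error-mutated 30 bp reads from random graph
paths, and align them:

```
$ graphaln generate --topology snp --seq-len 60 --seed 5 --snp-rate 0.1 -o demo.gfa
68 nodes, 75 edges -> demo.gfa
$ graphaln simulate-reads --graph demo.gfa --count 2 --length 30 \
      --sub-rate 0.05 --del-rate 0.03 --seed 11 -o demo.fasta
$ graphaln align --graph demo.gfa --reads demo.fasta --word-size 64 --crosscheck
read0  29  0  29  +  >30>31>32...>61>62  30  0  30  28  30  255  NM:i:2  cg:Z:13=1D6=1X9=
read1  30  0  30  +  >35>36>37...>66>67  30  0  30  29  30  255  NM:i:1  cg:Z:9=1X20=
```

Each GAF-style line reports the query span (always the whole read:
semi-global), the path through the graph in GFA segment orientations, the
number of matching bases (28 of 30 for `read0`), the edit distance
(`NM:i:2` — here one deletion and one substitution, visible in the
`cg:Z:13=1D6=1X9=` operation string). `--crosscheck` re-solves every read
with the Dijkstra oracle and fails on any disagreement.

The library interface exposes the same machinery; a read whose
substitutions sit on the alternative alleles of the bubbles aligns at
distance 0:

```python
>>> from graphaln import generate_snp, align_sliced, traceback
>>> g = generate_snp("GATTACAGATTACAGATTACA", snp_rate=0.2, seed=3)
>>> res = traceback(align_sliced(g, "GATTACAGTTTACA", word_size=64))
>>> res.edit_distance, res.cigar()
(0, '14=')
```

## Layout

| module | contents |
|---|---|
| `graphaln.graph` | sequence-graph model, GFA 1.0 I/O, linear/SNP/twopath/tangle generators, reverse-complement doubling, read simulation |
| `graphaln.shift_and` | pattern masks, multi-word NFA stepping, DAG and worklist matchers, witness-path extraction |
| `graphaln.columns` | `BitColumn` encode/decode, Myers step, reference and bit-parallel merges, changed-minimum |
| `graphaln.bucketqueue` | monotone bucket priority queue with decrease-key |
| `graphaln.align` | DAG / cyclic / sliced engines, traceback to CIGAR-style operations |
| `graphaln.oracle` | Dijkstra edit-graph solver, two-sweep cell-by-cell solver, reachability BFS |
| `graphaln.io`, `graphaln.cli` | FASTA/FASTQ ingestion, GAF-style output, `graphaln` command |
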