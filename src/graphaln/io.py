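"""Read ingestion and alignment output.

FASTA/FASTQ parsing goes through Biopython's SeqIO (format auto-detected
from the first record byte, gzip detected from magic bytes).  Alignments are
written in a GAF-style tab-separated format modeled on PAF: positions are
0-based half-open, the query is always aligned end-to-end (semi-global), and
the path column uses GFA segment orientations when the graph carries segment
provenance, node-id steps otherwise.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import IO, Iterator, Optional

from Bio import SeqIO

from .align import AlignmentResult
from .graph import DNA, GraphError, SequenceGraph, _IUPAC


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: Optional[str] = None  # parsed but never scored


def _open_maybe_gzip(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, iupac_as_n: bool = False) -> Iterator[ReadRecord]:
    """Stream reads from FASTA or FASTQ (plain or gzipped).

    Sequences are uppercased; characters outside ACGT raise under the strict
    policy, or map to 'N' with ``iupac_as_n`` ('N' matches nothing during
    alignment, so such positions can only appear as edits).
    """
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if not first:
            return
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise GraphError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        for rec in SeqIO.parse(handle, fmt):
            seq = str(rec.seq).upper()
            cleaned = []
            for c in seq:
                if c in DNA:
                    cleaned.append(c)
                elif iupac_as_n and (c in _IUPAC):
                    cleaned.append("N")
                else:
                    raise GraphError(
                        f"{path}: read {rec.id!r} has character {c!r} outside ACGT"
                    )
            if not cleaned:
                raise GraphError(f"{path}: read {rec.id!r} is empty")
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield ReadRecord(id=rec.id, sequence="".join(cleaned), quality=qual)


def _path_string(g: SequenceGraph, path: list[int]) -> str:
    if g.segment_map is None:
        return ">" + ">".join(str(v) for v in path)
    steps: list[str] = []
    for v in path:
        name, _, strand = g.segment_map[v]
        step = (">" if strand == "+" else "<") + name
        if not steps or steps[-1] != step:
            steps.append(step)
    return "".join(steps)


def gaf_line(g: SequenceGraph, res: AlignmentResult) -> str:
    """One GAF-style line: 12 PAF-like columns plus NM and cg tags."""
    m = res.query_length
    plen = len(res.path)
    fields = [
        res.query_id,
        str(m),
        "0",
        str(m),
        "+",
        _path_string(g, res.path),
        str(plen),
        "0",
        str(plen),
        str(res.matches),
        str(len(res.operations)),
        "255",
        f"NM:i:{res.edit_distance}",
        f"cg:Z:{res.cigar()}",
    ]
    return "\t".join(fields)


def write_gaf(results, g: SequenceGraph, path) -> None:
    with open(path, "w") as fh:
        for res in results:
            fh.write(gaf_line(g, res) + "\n")


def parse_gaf_line(line: str) -> dict:
    """Re-parse a GAF line (round-trip validation and tests)."""
    fields = line.rstrip("\n").split("\t")
    tags = {}
    for f in fields[12:]:
        name, typ, value = f.split(":", 2)
        tags[name] = int(value) if typ == "i" else value
    return {
        "query": fields[0],
        "query_length": int(fields[1]),
        "query_start": int(fields[2]),
        "query_end": int(fields[3]),
        "strand": fields[4],
        "path": fields[5],
        "path_length": int(fields[6]),
        "path_start": int(fields[7]),
        "path_end": int(fields[8]),
        "matches": int(fields[9]),
        "block_length": int(fields[10]),
        "tags": tags,
    }
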