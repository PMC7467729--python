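"""Toy-scale read mapping by exact k-mer anchoring and ungapped extension.

Each read is anchored by exact k-mer hits against an index of the
reference (both strands) and scored ungapped over its full length at every
candidate placement.  Reads with no anchors, or whose best placement has
too many mismatches, are left unmapped — reads spanning novel junctions
therefore fail to map and become the junction-sequencing reads consumed by
the assembler.  Reads whose best score is tied at more than one locus are
mapped but flagged non-unique and are excluded from depth profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import revcomp, seq_to_array
from .genome import ToyGenome
from .reads import ReadPair

DEFAULT_K = 21
#: anchors are taken every ANCHOR_STRIDE bases along the read
ANCHOR_STRIDE = 7
#: mapped iff mismatches <= this fraction of the read length
MAX_MISMATCH_FRAC = 0.10


@dataclass
class AlignmentRecord:
    """Ungapped placement of one read (or an unmapped placeholder)."""

    read_id: str
    mate: int  # 0 = /1, 1 = /2
    chrom: str | None
    start: int  # 0-based
    strand: str
    mapped: bool
    unique: bool
    edit_distance: int
    read_len: int

    @property
    def end(self) -> int:
        return self.start + self.read_len


class ReferenceIndex:
    """Exact k-mer index over the forward strands of a reference genome."""

    def __init__(self, genome: ToyGenome, k: int = DEFAULT_K):
        self.k = k
        self.genome = genome
        self.arrays = {c: seq_to_array(s) for c, s in genome.chromosomes.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self.index = index

    def candidates(self, read: str) -> set[tuple[str, int, str]]:
        """Candidate (chrom, start, strand) placements from k-mer anchors."""
        k = self.k
        out: set[tuple[str, int, str]] = set()
        for strand, seq in (("+", read), ("-", revcomp(read))):
            n = len(seq)
            positions = list(range(0, n - k + 1, ANCHOR_STRIDE))
            if positions and positions[-1] != n - k:
                positions.append(n - k)
            for i in positions:
                for chrom, p in self.index.get(seq[i : i + k], ()):
                    start = p - i
                    if 0 <= start <= len(self.arrays[chrom]) - n:
                        out.add((chrom, start, strand))
        return out


def map_read(index: ReferenceIndex, read_id: str, mate: int, read: str) -> AlignmentRecord:
    """Place one read; ties at the best score are flagged non-unique."""
    n = len(read)
    max_mm = int(MAX_MISMATCH_FRAC * n)
    best_mm = n + 1
    best: list[tuple[str, int, str]] = []
    fwd = seq_to_array(read)
    rev = seq_to_array(revcomp(read))
    for chrom, start, strand in index.candidates(read):
        arr = fwd if strand == "+" else rev
        mm = int(np.count_nonzero(index.arrays[chrom][start : start + n] != arr))
        if mm < best_mm:
            best_mm = mm
            best = [(chrom, start, strand)]
        elif mm == best_mm:
            best.append((chrom, start, strand))
    if not best or best_mm > max_mm:
        return AlignmentRecord(read_id, mate, None, -1, ".", False, False, -1, n)
    best.sort()
    chrom, start, strand = best[0]
    return AlignmentRecord(
        read_id, mate, chrom, start, strand,
        mapped=True, unique=(len(best) == 1), edit_distance=best_mm, read_len=n,
    )


def map_reads(
    genome: ToyGenome,
    pairs: Sequence[ReadPair],
    k: int = DEFAULT_K,
    index: ReferenceIndex | None = None,
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Map both mates of every pair against the reference."""
    if index is None:
        index = ReferenceIndex(genome, k=k)
    out = []
    for pair in pairs:
        r1 = map_read(index, pair.name, 0, pair.seq1)
        r2 = map_read(index, pair.name, 1, pair.seq2)
        out.append((r1, r2))
    return out


def is_concordant(
    a: AlignmentRecord,
    b: AlignmentRecord,
    insert_mean: float,
    insert_sd: float,
    n_sd: float = 3.0,
) -> bool:
    """FR orientation on one chromosome with a plausible implied insert."""
    if not (a.mapped and b.mapped) or a.chrom != b.chrom:
        return False
    if a.strand == b.strand:
        return False
    left, right = (a, b) if a.start <= b.start else (b, a)
    if left.strand != "+" or right.strand != "-":
        return False
    insert = right.end - left.start
    return abs(insert - insert_mean) <= n_sd * insert_sd


def write_sam(
    path: str | Path,
    genome: ToyGenome,
    alignments: Sequence[tuple[AlignmentRecord, AlignmentRecord]],
    pairs: Sequence[ReadPair] | None = None,
) -> None:
    """Minimal 11-mandatory-field SAM (1-based) with NM tags."""
    seqs: dict[str, tuple[str, str]] = {}
    if pairs is not None:
        seqs = {p.name: (p.seq1, p.seq2) for p in pairs}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for a, b in alignments:
            for rec, other in ((a, b), (b, a)):
                flag = 1  # paired
                flag |= 64 if rec.mate == 0 else 128
                if not rec.mapped:
                    flag |= 4
                if other is not None and not other.mapped:
                    flag |= 8
                if rec.mapped and rec.strand == "-":
                    flag |= 16
                if other is not None and other.mapped and other.strand == "-":
                    flag |= 32
                rname = rec.chrom if rec.mapped else "*"
                pos = rec.start + 1 if rec.mapped else 0
                cigar = f"{rec.read_len}M" if rec.mapped else "*"
                rnext = "*"
                pnext = 0
                if other is not None and other.mapped:
                    rnext = "=" if other.chrom == rec.chrom else other.chrom
                    pnext = other.start + 1
                seq = "*"
                if rec.read_id in seqs:
                    raw = seqs[rec.read_id][rec.mate]
                    seq = revcomp(raw) if (rec.mapped and rec.strand == "-") else raw
                qual = "I" * rec.read_len if seq != "*" else "*"
                tags = f"\tNM:i:{rec.edit_distance}" if rec.mapped else ""
                fh.write(
                    f"{rec.read_id}\t{flag}\t{rname}\t{pos}\t"
                    f"{255 if rec.unique else 0}\t{cigar}\t{rnext}\t{pnext}\t0\t"
                    f"{seq}\t{qual}{tags}\n"
                )
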