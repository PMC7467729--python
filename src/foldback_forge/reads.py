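"""Paired-end short-read simulation from toy genomes.

FR-oriented pairs are drawn uniformly over each chromosome with Gaussian
fragment lengths and independent per-base substitution errors.  Read names
encode the true origin (chromosome, fragment start, strand) so downstream
stages can be scored against truth without auxiliary files.  Base
qualities are constant (no quality model); indel errors are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from ._rng import substream
from ._seq import array_to_seq, revcomp_array, seq_to_array
from .genome import ToyGenome


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    seq2: str


def simulate_reads(
    genome: ToyGenome,
    coverage: float,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    seed: int | np.random.Generator = 0,
) -> list[ReadPair]:
    """Simulate FR paired-end reads at the requested fold coverage.

    Fragment starts are uniform per chromosome; fragment lengths are
    normal(insert_mean, insert_sd) clipped to [read_length, chromosome
    length]; each fragment is sequenced from a uniformly chosen strand.
    Read 1 is the fragment's 5' end, read 2 the reverse complement of its
    3' end.  Substitution errors occur independently at ``error_rate``.
    """
    if read_length >= insert_mean:
        raise ValueError("read_length must be below insert_mean")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else substream(int(seed), "reads")
    )

    pairs: list[ReadPair] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        if insert_mean >= L:
            raise ValueError(f"insert_mean {insert_mean} >= length of {chrom} ({L})")
        arr = seq_to_array(seq)
        n_pairs = int(round(coverage * L / (2 * read_length)))
        flens = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)),
            read_length,
            L,
        ).astype(np.int64)
        starts = rng.integers(0, L - flens + 1)
        strands = rng.integers(0, 2, size=n_pairs)  # 0 = '+', 1 = '-'
        n_err = (
            rng.binomial(2 * read_length, error_rate, size=n_pairs)
            if error_rate > 0
            else np.zeros(n_pairs, dtype=np.int64)
        )
        for i in range(n_pairs):
            s, fl = int(starts[i]), int(flens[i])
            frag = arr[s : s + fl]
            if strands[i] == 1:
                frag = revcomp_array(frag)
            r1 = frag[:read_length].copy()
            r2 = revcomp_array(frag[fl - read_length :]).copy()
            if n_err[i] > 0:
                _inject_errors(r1, r2, int(n_err[i]), rng)
            strand = "-" if strands[i] else "+"
            pairs.append(
                ReadPair(
                    name=f"sim:{chrom}:{s}:{fl}:{strand}:{i}",
                    seq1=array_to_seq(r1),
                    seq2=array_to_seq(r2),
                )
            )
    return pairs


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _inject_errors(
    r1: np.ndarray, r2: np.ndarray, n_err: int, rng: np.random.Generator
) -> None:
    rl = len(r1)
    for pos in rng.integers(0, 2 * rl, size=n_err):
        read = r1 if pos < rl else r2
        p = int(pos % rl)
        choices = _BASE_BYTES[_BASE_BYTES != read[p]]
        read[p] = choices[rng.integers(0, len(choices))]


def write_fastq_pair(
    pairs: Sequence[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write Illumina-style /1 and /2 FASTQ files (constant quality)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            q2 = "I" * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


def read_fastq_pair(path_r1: str | Path, path_r2: str | Path) -> list[ReadPair]:
    """Read paired FASTQ files back into ReadPair records."""
    reads1 = dict(_iter_fastq(path_r1))
    reads2 = dict(_iter_fastq(path_r2))
    if reads1.keys() != reads2.keys():
        raise ValueError("R1/R2 read names do not match")
    return [ReadPair(name, reads1[name], reads2[name]) for name in reads1]


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            record += 1
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ at record {record} in {path}")
            name = header[1:].strip()
            if name.endswith("/1") or name.endswith("/2"):
                name = name[:-2]
            yield name, seq.strip().upper()
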