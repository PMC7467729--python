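"""Read-depth and span-depth profiles and copy-number segmentation.

*Read depth* at a base is the number of times it was read; *span depth*
additionally counts bases spanned by the inter-mate gap of concordant
pairs.  Both use uniquely mapped reads only.  Read depth drives copy
number (it is less distorted near repeats); span depth drives the
noise filter for junction-defining discordant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import ToyGenome
from .mapping import AlignmentRecord, is_concordant


@dataclass
class DepthProfile:
    chromosome: str
    read_depth: np.ndarray
    span_depth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.read_depth) != len(self.span_depth):
            raise ValueError("profile arrays must have equal length")


def compute_depths(
    alignments: Sequence[tuple[AlignmentRecord, AlignmentRecord]],
    genome: ToyGenome,
    insert_mean: float,
    insert_sd: float,
) -> dict[str, DepthProfile]:
    """Per-chromosome read-depth and span-depth from unique alignments."""
    read_diff = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in genome.chromosomes.items()}
    span_diff = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in genome.chromosomes.items()}

    def add(diff: dict, chrom: str, start: int, end: int) -> None:
        L = len(diff[chrom]) - 1
        if start < 0 or end > L:
            raise ValueError(f"alignment [{start},{end}) outside {chrom} (len {L})")
        diff[chrom][start] += 1
        diff[chrom][end] -= 1

    for a, b in alignments:
        for rec in (a, b):
            if rec.mapped and rec.unique:
                add(read_diff, rec.chrom, rec.start, rec.end)
        if a.mapped and b.mapped and a.unique and b.unique and is_concordant(
            a, b, insert_mean, insert_sd
        ):
            gap_lo = min(a.end, b.end)
            gap_hi = max(a.start, b.start)
            if gap_lo < gap_hi:  # inter-mate gap (mates may overlap)
                add(span_diff, a.chrom, gap_lo, gap_hi)

    out = {}
    for chrom in genome.chromosomes:
        rd = np.cumsum(read_diff[chrom][:-1])
        gap = np.cumsum(span_diff[chrom][:-1])
        out[chrom] = DepthProfile(chrom, rd, rd + gap)
    return out


def genome_median_depth(profiles: dict[str, DepthProfile]) -> float:
    """Median per-base read depth over all chromosomes (copy-1 baseline)."""
    depths = np.concatenate([p.read_depth for p in profiles.values()])
    return float(np.median(depths))


@dataclass(frozen=True)
class CopySegment:
    chromosome: str
    start: int
    end: int
    copy_number: int
    mean_depth: float


def segment_copy_number(
    profile: DepthProfile,
    median_depth: float,
    min_segment: int = 200,
    t_threshold: float = 12.0,
    edge_margin: int = 300,
    merge_below: int = 500,
) -> list[CopySegment]:
    """Recursive binary segmentation of the read-depth profile.

    Each candidate split maximises a t-like statistic for the difference
    of segment means; recursion stops when the best split's statistic
    falls below ``t_threshold`` or a part would be shorter than
    ``min_segment``.  The outermost ``edge_margin`` bases are excluded
    from splitting (coverage ramps down toward chromosome ends at about
    one insert length).  Segment copy number is the segment mean divided
    by the genome-wide median depth, rounded; adjacent equal-copy
    segments are merged, and segments shorter than ``merge_below`` are
    absorbed into the neighbour with the closer mean — per-base depth is
    autocorrelated over the read length, which inflates the split
    statistic and produces short spurious segments otherwise.
    """
    x_full = profile.read_depth.astype(np.float64)
    n_full = len(x_full)
    if n_full < 2 * min_segment:
        raise ValueError("profile shorter than twice min_segment")
    if np.all(x_full == 0):
        return [CopySegment(profile.chromosome, 0, n_full, 0, 0.0)]

    margin = min(edge_margin, max(0, (n_full - 2 * min_segment) // 2))
    x = x_full[margin : n_full - margin]
    n = len(x)

    boundaries: list[int] = [0, n]

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        m = len(seg)
        if m < 2 * min_segment:
            return
        csum = np.cumsum(seg)
        csq = np.cumsum(seg * seg)
        ks = np.arange(min_segment, m - min_segment + 1, dtype=np.int64)
        left_sum = csum[ks - 1]
        tot = csum[-1]
        left_n = ks.astype(np.float64)
        right_n = (m - ks).astype(np.float64)
        mean_l = left_sum / left_n
        mean_r = (tot - left_sum) / right_n
        ss_l = csq[ks - 1] - left_sum**2 / left_n
        ss_r = (csq[-1] - csq[ks - 1]) - (tot - left_sum) ** 2 / right_n
        pooled_var = (ss_l + ss_r) / np.maximum(m - 2, 1)
        se = np.sqrt(np.maximum(pooled_var, 1e-9) * (1 / left_n + 1 / right_n))
        t = np.abs(mean_l - mean_r) / se
        k_best = int(np.argmax(t))
        if t[k_best] < t_threshold:
            return
        split = lo + int(ks[k_best])
        boundaries.append(split)
        recurse(lo, split)
        recurse(split, hi)

    recurse(0, n)
    # re-anchor boundaries on the full profile; outer segments absorb the
    # excluded edge margins
    boundaries = sorted({0, n_full} | {b + margin for b in boundaries if 0 < b < n})

    baseline = max(median_depth, 1e-9)
    raw: list[tuple[int, int, float]] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        in_lo = min(max(lo, margin), n_full - margin)
        in_hi = max(min(hi, n_full - margin), in_lo + 1)
        raw.append((lo, hi, float(x_full[in_lo:in_hi].mean())))

    # absorb short spurious segments into the closer-mean neighbour
    changed = True
    while changed and len(raw) > 1:
        changed = False
        for i, (lo, hi, mean) in enumerate(raw):
            if hi - lo >= merge_below:
                continue
            neighbours = []
            if i > 0:
                neighbours.append(i - 1)
            if i < len(raw) - 1:
                neighbours.append(i + 1)
            j = min(neighbours, key=lambda j: abs(raw[j][2] - mean))
            a, b = sorted((i, j))
            (lo1, hi1, m1), (lo2, hi2, m2) = raw[a], raw[b]
            w1, w2 = hi1 - lo1, hi2 - lo2
            raw[a : b + 1] = [(lo1, hi2, (m1 * w1 + m2 * w2) / (w1 + w2))]
            changed = True
            break

    segments: list[CopySegment] = []
    for lo, hi, mean in raw:
        cn = int(round(mean / baseline))
        if segments and segments[-1].copy_number == cn:
            prev = segments.pop()
            w1, w2 = prev.end - prev.start, hi - lo
            mean = (prev.mean_depth * w1 + mean * w2) / (w1 + w2)
            lo = prev.start
        segments.append(CopySegment(profile.chromosome, lo, hi, cn, mean))
    return segments


def write_bedgraph(path: str | Path, profiles: dict[str, DepthProfile], which: str = "read_depth") -> None:
    """bedGraph (0-based half-open) of a depth profile, run-length encoded."""
    with open(path, "w") as fh:
        for chrom, prof in profiles.items():
            arr = getattr(prof, which)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(arr[s])}\n")


def write_segments_bed(path: str | Path, segments: Sequence[CopySegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chromosome}\t{seg.start}\t{seg.end}\tCN{seg.copy_number}\t"
                f"{seg.mean_depth:.2f}\t.\n"
            )
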