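"""Hairpin-forming inverted repeats: enumeration, inference and summaries.

A single-stranded DNA hairpin forms when two inverted complementary "arms"
of one strand pair into a *stem* (length in bp), separated by an unpaired
*loop* (length in nt).  Foldback inversion GCRs initiate at such sites, so
this module provides:

* :func:`enumerate_hairpin_sites` — scan a sequence for all maximal perfect
  inverted repeats under stem/loop constraints (loop < 50 nt, no stem
  mismatches), the rule used to catalogue candidate sites in a breakpoint
  region;
* :func:`infer_hairpin_from_junction` — recover stem and loop geometry from
  an observed inversion junction on the reference, optionally allowing
  mispairs/unpaired bases in the stem via local alignment;
* :func:`classify_loop` and :func:`loop_size_summary` — the short (<15 nt)
  versus large-loop dichotomy and per-event / per-site loop distributions;
* :func:`rank_hairpins_near_dsb` — order candidate sites by their propensity
  to mediate a foldback from a given double-strand break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from ._seq import check_dna, complement, revcomp

#: loop length (nt) separating "short" from "large" loops
LOOP_CLASS_THRESHOLD = 15

#: smallest stem considered interpretable when inferring from a junction
MIN_INFERRED_STEM = 4


class HairpinNotFoundError(ValueError):
    """No hairpin with a stem of at least MIN_INFERRED_STEM is inferable."""


@dataclass(frozen=True)
class HairpinSite:
    """A perfect inverted repeat able to fold into an ssDNA hairpin.

    Coordinates are 0-based half-open on the scanned sequence. ``arm1`` is
    the telomeric (left) arm, ``arm2`` the centromeric (right) arm, and
    ``arm2`` sequence is the exact reverse complement of ``arm1`` when
    ``perfect_stem`` is set.
    """

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    stem_len: int
    loop_len: int
    perfect_stem: bool = True
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.arm1[1] > self.arm2[0]:
            raise ValueError("arm2 must start after arm1 ends")
        if self.arm2[0] - self.arm1[1] != self.loop_len:
            raise ValueError("loop_len must equal the gap between arms")
        if (self.arm1[1] - self.arm1[0]) != self.stem_len or (
            self.arm2[1] - self.arm2[0]
        ) != self.stem_len:
            raise ValueError("stem_len must equal both arm lengths")

    @property
    def center(self) -> int:
        return (self.arm1[0] + self.arm2[1]) // 2

    @property
    def span(self) -> tuple[int, int]:
        return (self.arm1[0], self.arm2[1])


@dataclass(frozen=True)
class HairpinInference:
    """Hairpin geometry inferred from an inversion junction."""

    pos_a: int
    pos_b: int
    stem_len: int
    loop_len: int
    n_mispairs: int = 0
    n_unpaired: int = 0
    chromosome: str | None = None

    @property
    def imperfect(self) -> bool:
        return (self.n_mispairs + self.n_unpaired) > 0


LoopClass = Literal["short", "large"]


def classify_loop(loop_len: int) -> LoopClass:
    """Classify a hairpin loop as short (<15 nt) or large (>=15 nt)."""
    if loop_len < 0:
        raise ValueError(f"loop length must be non-negative, got {loop_len}")
    return "short" if loop_len < LOOP_CLASS_THRESHOLD else "large"


def enumerate_hairpin_sites(
    sequence: str,
    min_stem: int,
    max_loop: int = 49,
    min_loop: int = 3,
    chromosome: str | None = None,
) -> list[HairpinSite]:
    """All maximal perfect inverted repeats with the given geometry bounds.

    A site is *maximal* when neither arm can be extended outward while
    preserving perfect complementarity, and the arms cannot be extended
    inward (shrinking the loop by two) while keeping the loop at
    ``min_loop`` or more.  Overlapping sites are deduplicated keeping the
    longest stem, ties broken by smaller loop then leftmost center; the
    survivors are returned sorted by center.
    """
    if min_stem < 2:
        raise ValueError("min_stem must be >= 2")
    if min_loop > max_loop:
        raise ValueError("min_loop must be <= max_loop")
    check_dna(sequence)
    n = len(sequence)
    comp = complement(sequence)

    candidates: list[HairpinSite] = []
    for loop_start in range(1, n):
        for loop_len in range(min_loop, max_loop + 1):
            arm2_start = loop_start + loop_len
            if arm2_start >= n:
                break
            # inward maximality: a smaller-loop site at this center covers it
            if loop_len - 2 >= min_loop and sequence[loop_start] == comp[arm2_start - 1]:
                continue
            s = 0
            while (
                loop_start - s - 1 >= 0
                and arm2_start + s < n
                and sequence[loop_start - s - 1] == comp[arm2_start + s]
            ):
                s += 1
            if s >= min_stem:
                candidates.append(
                    HairpinSite(
                        arm1=(loop_start - s, loop_start),
                        arm2=(arm2_start, arm2_start + s),
                        stem_len=s,
                        loop_len=loop_len,
                        perfect_stem=True,
                        chromosome=chromosome,
                    )
                )

    return _dedupe_sites(candidates)


def _dedupe_sites(candidates: list[HairpinSite]) -> list[HairpinSite]:
    """Keep the best site among overlapping spans.

    Priority: longer stem, then smaller loop, then leftmost center.
    """
    kept: list[HairpinSite] = []
    for site in sorted(candidates, key=lambda h: (-h.stem_len, h.loop_len, h.center)):
        lo, hi = site.span
        if any(lo < k.span[1] and k.span[0] < hi for k in kept):
            continue
        kept.append(site)
    kept.sort(key=lambda h: h.center)
    return kept


def infer_hairpin_from_junction(
    reference: str,
    junction: tuple[int, int],
    allow_imperfect: bool = False,
    window: int = 60,
    chromosome: str | None = None,
) -> HairpinInference:
    """Infer stem/loop geometry of the hairpin behind an inversion junction.

    ``junction`` is the pair of reference breakpoints flanking the inversion
    center (0-based; order-insensitive): for a hairpin-mediated junction
    these are the inner ends of the two arms.  The sequence centromeric to
    ``pos_b`` is compared with the reverse complement of the sequence
    telomeric to ``pos_a``; the aligned run is the stem and the unaligned
    gap between the arm inner ends is the loop.

    With ``allow_imperfect`` the comparison is a local alignment (match +1,
    mispair -1, gap -2) so mispaired and unpaired stem bases are tolerated
    and counted; otherwise the stem is the maximal exact complementary run.
    """
    pos_a, pos_b = sorted(int(p) for p in junction)
    if not (0 <= pos_a <= len(reference) and 0 <= pos_b <= len(reference)):
        raise ValueError("junction positions outside the reference")

    a_side = reference[pos_b : pos_b + window]
    b_side = revcomp(reference[max(0, pos_a - window) : pos_a])

    if not allow_imperfect:
        s = 0
        while s < min(len(a_side), len(b_side)) and a_side[s] == b_side[s]:
            s += 1
        if s < MIN_INFERRED_STEM:
            raise HairpinNotFoundError(
                f"no hairpin inferable at {junction}: maximal perfect stem {s} "
                f"< {MIN_INFERRED_STEM} bp"
            )
        return HairpinInference(
            pos_a=pos_a,
            pos_b=pos_b,
            stem_len=s,
            loop_len=pos_b - pos_a,
            n_mispairs=0,
            n_unpaired=0,
            chromosome=chromosome,
        )

    aln = _best_local_alignment(a_side, b_side)
    if aln is None or aln.score < MIN_INFERRED_STEM:
        raise HairpinNotFoundError(
            f"no hairpin inferable at {junction}: best stem score below "
            f"{MIN_INFERRED_STEM}"
        )
    start_a, start_b, n_match, n_mispair, n_gap = aln.counts
    stem_len = n_match + n_mispair + n_gap
    loop_len = (pos_b - pos_a) + start_a + start_b
    return HairpinInference(
        pos_a=pos_a,
        pos_b=pos_b,
        stem_len=stem_len,
        loop_len=loop_len,
        n_mispairs=n_mispair,
        n_unpaired=n_gap,
        chromosome=chromosome,
    )


class _Alignment:
    def __init__(self, score: float, counts: tuple[int, int, int, int, int]):
        self.score = score
        self.counts = counts


def _best_local_alignment(a: str, b: str) -> _Alignment | None:
    """Best local alignment of a vs b (match +1 / mispair -1 / gap -2)."""
    if not a or not b:
        return None
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alns = aligner.align(a, b)
    try:
        best = alns[0]
    except IndexError:
        return None
    # walk the aligned blocks to count matches / mispairs / gap columns
    n_match = n_mispair = n_gap = 0
    blocks_a, blocks_b = best.aligned
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            n_gap += (sa - prev_a) + (sb - prev_b)
        for i, j in zip(range(sa, ea), range(sb, eb)):
            if a[i] == b[j]:
                n_match += 1
            else:
                n_mispair += 1
        prev_a, prev_b = ea, eb
    start_a = int(blocks_a[0][0])
    start_b = int(blocks_b[0][0])
    return _Alignment(best.score, (start_a, start_b, n_match, n_mispair, n_gap))


@dataclass
class LoopSummary:
    """Loop-size distribution with median and cumulative curve."""

    mode: str
    counts: dict[int, int]
    median: float
    #: (loop length, cumulative fraction of observations <= that length)
    cumulative: list[tuple[int, float]] = field(repr=False, default_factory=list)
    n: int = 0


def loop_size_summary(
    inferences: Sequence[HairpinInference],
    mode: Literal["per_event", "per_site"] = "per_event",
) -> LoopSummary:
    """Summarise loop sizes counting every rearrangement or every site once.

    ``per_event`` counts each inference; ``per_site`` collapses inferences
    with identical (chromosome, pos_a, pos_b) to a single observation.  The
    median uses the midpoint-of-two-middle-values convention for even n.
    """
    if not inferences:
        raise ValueError("empty inference list")
    if mode == "per_site":
        seen: dict[tuple, HairpinInference] = {}
        for inf in inferences:
            seen.setdefault((inf.chromosome, inf.pos_a, inf.pos_b), inf)
        items: Iterable[HairpinInference] = seen.values()
    elif mode == "per_event":
        items = inferences
    else:
        raise ValueError(f"unknown mode {mode!r}")

    loops = sorted(inf.loop_len for inf in items)
    counts: dict[int, int] = {}
    for l in loops:
        counts[l] = counts.get(l, 0) + 1
    n = len(loops)
    cum: list[tuple[int, float]] = []
    running = 0
    for l in sorted(counts):
        running += counts[l]
        cum.append((l, running / n))
    return LoopSummary(
        mode=mode,
        counts=counts,
        median=float(np.median(loops)),
        cumulative=cum,
        n=n,
    )


def rank_hairpins_near_dsb(
    sites: Sequence[HairpinSite],
    dsb_pos: int,
    window: int = 50,
) -> list[HairpinSite]:
    """Rank candidate hairpin sites by foldback propensity from a DSB.

    Observed foldbacks tend to use hairpins within ~50 bp of the break;
    among those, longer stems and shorter loops dominate.  Sites within
    ``window`` of the DSB are ranked by (longer stem, shorter loop, smaller
    distance); the rest follow, ranked by stem length alone.
    """
    def distance(site: HairpinSite) -> int:
        return abs(site.center - dsb_pos)

    near = [s for s in sites if distance(s) <= window]
    far = [s for s in sites if distance(s) > window]
    near.sort(key=lambda s: (-s.stem_len, s.loop_len, distance(s)))
    far.sort(key=lambda s: -s.stem_len)
    return near + far
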