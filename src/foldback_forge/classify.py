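"""GCR taxonomy: event types, foldback resolution classes and spectra.

A foldback inversion is called when all four signature features are
present: (1) a deletion spanning some or all of the counter-selected
cassette, (2) a duplicated (copy-2) segment extending centromerically
from the deletion, (3) a validated inversion-geometry junction at the
telomeric edge of the duplication, and (4) an assembled sequence across
that junction.  Foldback resolution products fall into three classes —
SSA capture through an inverted homology pair (captured fragment at copy
1), a single homology-mediated rearrangement duplicating a donor
telomeric segment (copy 2), or complex multi-junction products — plus
de novo telomere addition and microhomology-mediated joins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .depth import CopySegment
from .genome import Feature, ToyGenome
from .hairpin import HairpinInference, classify_loop, infer_hairpin_from_junction
from .hairpin import HairpinNotFoundError
from .junctions import JunctionCall

EventCall = Literal[
    "foldback_inversion",
    "telomere_addition",
    "mh_translocation",
    "interstitial_deletion",
    "complex",
    "none",
]

ResolutionClass = Literal[
    "class1_ssa_capture",
    "class2_homology_translocation",
    "class3_complex",
    "telomere_addition_resolution",
    "microhomology_resolution",
]

#: junction-to-segment-edge tolerance, matched to segmentation resolution
EDGE_TOLERANCE = 200
#: microhomology ceiling separating microhomology- from homology-mediated
MH_CEILING = 10


@dataclass
class GCRClassification:
    event_type: EventCall
    evidence: list[str] = field(default_factory=list)
    hairpin: HairpinInference | None = None
    loop_class: str | None = None
    primary_junction: JunctionCall | None = None
    secondary_junctions: list[JunctionCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_type == "foldback_inversion" and self.hairpin is None:
            raise ValueError("foldback calls must carry a hairpin inference")


def _validated(junctions: Sequence[JunctionCall]) -> list[JunctionCall]:
    return [j for j in junctions if j.validated]


def classify_gcr(
    junctions: Sequence[JunctionCall],
    segments: Sequence[CopySegment],
    genome: ToyGenome,
    assay_chrom: str = "chr1",
) -> GCRClassification:
    """Classify one isolate's validated junctions + segments into a GCR call."""
    for j in junctions:
        for bp in (j.breakpoint_a, j.breakpoint_b):
            if bp is not None and bp.chrom not in genome.chromosomes:
                raise ValueError(f"junction references unknown chromosome {bp.chrom}")
    calls = sorted(
        _validated(junctions),
        key=lambda j: (
            j.breakpoint_a.chrom if j.breakpoint_a else "",
            j.breakpoint_a.pos if j.breakpoint_a else -1,
        ),
    )
    calls = _dedupe_calls(calls)
    if not calls:
        return GCRClassification(event_type="none")

    cassette = next(
        (f for f in genome.features_of("cassette", assay_chrom)), None
    )
    assay_segments = [s for s in segments if s.chromosome == assay_chrom]

    foldback = _try_foldback(calls, assay_segments, cassette, genome, assay_chrom)
    if foldback is not None:
        return foldback

    primary = calls[0]
    extras = calls[1:]
    if len(extras) >= 2:
        return GCRClassification(
            event_type="complex", primary_junction=primary,
            secondary_junctions=extras,
            evidence=[f"{len(calls)} validated junctions"],
        )

    if primary.b_is_telomere:
        return GCRClassification(
            event_type="telomere_addition",
            primary_junction=primary,
            secondary_junctions=extras,
            evidence=[f"{primary.n_telomere_units} tandem telomere units at junction"],
        )
    geom = primary.cluster.geometry
    if geom == "translocation":
        return GCRClassification(
            event_type="mh_translocation",
            primary_junction=primary,
            secondary_junctions=extras,
            evidence=[f"inter-chromosomal junction, mh={primary.microhomology_len}"],
        )
    if geom == "deletion_like":
        return GCRClassification(
            event_type="interstitial_deletion",
            primary_junction=primary,
            secondary_junctions=extras,
            evidence=[f"intra-chromosomal deletion junction, mh={primary.microhomology_len}"],
        )
    return GCRClassification(
        event_type="complex" if extras else "none",
        primary_junction=primary,
        secondary_junctions=extras,
        evidence=[f"unassigned geometry {geom}"],
    )


def _dedupe_calls(calls: list[JunctionCall]) -> list[JunctionCall]:
    """Collapse calls describing the same junction, keeping the best support."""
    best: dict[tuple, JunctionCall] = {}
    for j in calls:
        key = tuple(
            (bp.chrom, bp.pos, bp.strand) if bp is not None else None
            for bp in sorted(
                (x for x in (j.breakpoint_a, j.breakpoint_b) if x is not None),
                key=lambda b: (b.chrom, b.pos),
            )
        ) + (j.b_is_telomere,)
        prev = best.get(key)
        if prev is None or j.n_support_pairs > prev.n_support_pairs:
            best[key] = j
    return list(best.values())


def _try_foldback(
    calls: list[JunctionCall],
    segments: Sequence[CopySegment],
    cassette: Feature | None,
    genome: ToyGenome,
    assay_chrom: str,
) -> GCRClassification | None:
    if cassette is None:
        return None
    evidence = []
    deleted = [
        s for s in segments
        if s.copy_number == 0 and s.start < cassette.end and cassette.start < s.end
    ]
    if not deleted:
        return None
    evidence.append("deletion spanning the counter-selected cassette")
    deletion = max(deleted, key=lambda s: s.end - s.start)

    dups = [s for s in segments if s.copy_number >= 2 and s.start >= deletion.start]
    if not dups:
        return None
    dup = min(dups, key=lambda s: s.start)
    evidence.append(
        f"copy-{dup.copy_number} duplication [{dup.start},{dup.end}) centromeric of the deletion"
    )

    inv = None
    for j in calls:
        if j.cluster.geometry != "inversion" or j.coarse:
            continue
        ba, bb = j.breakpoint_a, j.breakpoint_b
        if ba is None or bb is None or ba.chrom != assay_chrom:
            continue
        edge = min(ba.pos, bb.pos)
        # the junction sits at the duplication's telomeric boundary, which
        # segmentation places between the deletion's end and the copy-2
        # segment's start (coverage ramps blur the transition)
        if (
            abs(edge - dup.start) <= EDGE_TOLERANCE
            or abs(edge - deletion.end) <= EDGE_TOLERANCE
            or deletion.end - EDGE_TOLERANCE <= edge <= dup.start + EDGE_TOLERANCE
        ):
            inv = j
            break
    if inv is None:
        return None
    evidence.append("validated inversion-geometry junction at the duplication's telomeric edge")
    if not inv.contig:
        return None
    evidence.append("junction sequence assembled across the inversion point")

    try:
        hairpin = infer_hairpin_from_junction(
            genome.chromosomes[assay_chrom],
            (inv.breakpoint_a.pos, inv.breakpoint_b.pos),
            allow_imperfect=False,
        )
    except HairpinNotFoundError:
        try:
            hairpin = infer_hairpin_from_junction(
                genome.chromosomes[assay_chrom],
                (inv.breakpoint_a.pos, inv.breakpoint_b.pos),
                allow_imperfect=True,
            )
        except HairpinNotFoundError:
            return None
    extras = [j for j in calls if j is not inv]
    return GCRClassification(
        event_type="foldback_inversion",
        evidence=evidence,
        hairpin=hairpin,
        loop_class=classify_loop(hairpin.loop_len),
        primary_junction=inv,
        secondary_junctions=extras,
    )


def classify_resolution(
    classification: GCRClassification,
    segments: Sequence[CopySegment],
    genome: ToyGenome,
    assay_chrom: str = "chr1",
) -> ResolutionClass:
    """Assign a foldback inversion's secondary-resolution class."""
    if classification.event_type != "foldback_inversion":
        raise ValueError("resolution classes apply to foldback inversions only")
    extras = classification.secondary_junctions
    if len(extras) >= 2:
        return "class3_complex"

    if len(extras) == 1:
        sec = extras[0]
        if sec.b_is_telomere:
            return "telomere_addition_resolution"
        homs = _junction_features(sec, genome, ("homology_block",))
        reps = _junction_features(sec, genome, ("repeat_element",))
        if homs and _is_inverted_pair_join(sec, homs):
            if _captured_copy_number(sec, segments, genome, assay_chrom) == 1:
                return "class1_ssa_capture"
        if (homs or reps) and _donor_telomeric_copy(sec, segments) >= 2:
            return "class2_homology_translocation"
        if sec.microhomology_len <= MH_CEILING and not (homs or reps):
            return "microhomology_resolution"
        # homology overlap without the expected copy-number signature:
        # fall through to the microhomology bucket only if mh is small
        if sec.microhomology_len <= MH_CEILING:
            return "microhomology_resolution"
        return "class2_homology_translocation"

    # no secondary junction: the inverted duplication must end in telomere
    return "telomere_addition_resolution"


def _junction_features(
    call: JunctionCall, genome: ToyGenome, kinds: tuple[str, ...]
) -> list[Feature]:
    out = []
    # coarse calls carry anchor-resolution breakpoints (~ one insert length)
    pad = 350 if call.coarse else 10
    for bp in (call.breakpoint_a, call.breakpoint_b):
        if bp is None:
            continue
        for f in genome.features:
            if f.kind in kinds and f.chromosome == bp.chrom:
                if f.start - pad - call.microhomology_len <= bp.pos <= f.end + pad + call.microhomology_len:
                    out.append(f)
    return out


def _is_inverted_pair_join(call: JunctionCall, feats: list[Feature]) -> bool:
    names = {f.name.rsplit("_", 1)[0] for f in feats}
    return len(feats) >= 2 and len(names) == 1


def _captured_copy_number(
    sec: JunctionCall,
    segments: Sequence[CopySegment],
    genome: ToyGenome,
    assay_chrom: str,
) -> int:
    """Copy number of the captured telomeric fragment beyond the junction.

    The captured side is the breakpoint nearer its chromosome start (the
    telomeric homology member); strand labels are not used because the
    assembled contig's orientation — and with it the strand labelling —
    is arbitrary when the junction carries no microhomology.
    """
    bps = [bp for bp in (sec.breakpoint_a, sec.breakpoint_b) if bp is not None]
    if not bps:
        return 0
    tol = 350 if sec.coarse else EDGE_TOLERANCE
    bp = min(bps, key=lambda b: b.pos)
    telomeric = [
        s for s in segments
        if s.chromosome == bp.chrom and s.end <= bp.pos + tol and s.copy_number > 0
    ]
    if not telomeric:
        return 0
    return max(s.copy_number for s in telomeric)


def _donor_telomeric_copy(sec: JunctionCall, segments: Sequence[CopySegment]) -> int:
    """Copy number of the donor's captured telomeric segment.

    A homology-mediated translocation duplicates the donor chromosome
    from the target element out to its telomere, so the qualifying
    segment must be anchored at the chromosome end (start near 0), not
    merely any duplicated interval near the junction.
    """
    best = 0
    tol = 350 if sec.coarse else EDGE_TOLERANCE
    for bp in (sec.breakpoint_a, sec.breakpoint_b):
        if bp is None:
            continue
        for s in segments:
            if (
                s.chromosome == bp.chrom
                and s.start <= tol
                and s.end <= bp.pos + 2 * tol
                and bp.pos - s.end <= 2 * tol
                and s.copy_number > best
            ):
                best = s.copy_number
    return best


def measure_microhomology(junction: str, flank_a: str, flank_b: str) -> int:
    """Microhomology at a junction from its two reference flanks.

    ``flank_a`` is reference sequence aligned to the start of the junction
    string (continuing through and past the side-A breakpoint), ``flank_b``
    reference sequence aligned to its end.  The maximal run of junction
    bases claimable by both flanks — side A's match extended forward
    overlapping side B's match extended backward — is the microhomology.
    """
    if len(flank_a) < 15 or len(flank_b) < 15:
        raise ValueError("flanks must be at least 15 bp")
    i_a = 0
    for x, y in zip(junction, flank_a):
        if x != y:
            break
        i_a += 1
    i_b = len(junction)
    for x, y in zip(reversed(junction), reversed(flank_b)):
        if x != y:
            break
        i_b -= 1
    return max(0, i_a - i_b)


def spectrum_table(
    classifications: Sequence[GCRClassification],
    resolutions: Sequence[ResolutionClass | None] | None = None,
) -> dict:
    """Category counts by event type, loop class and resolution class.

    Returns a dict with ``event_counts``, ``loop_class_counts`` and
    ``resolution_counts`` Counters plus the foldback/other 2x2-ready
    marginals consumed by the spectrum-comparison tests.
    """
    if not classifications:
        raise ValueError("need at least one classification")
    event_counts = Counter(c.event_type for c in classifications)
    loop_counts = Counter(
        c.loop_class for c in classifications if c.loop_class is not None
    )
    res_counts: Counter = Counter()
    if resolutions is not None:
        res_counts = Counter(r for r in resolutions if r is not None)
    n = len(classifications)
    k_foldback = event_counts.get("foldback_inversion", 0)
    return {
        "n": n,
        "event_counts": dict(event_counts),
        "loop_class_counts": dict(loop_counts),
        "resolution_counts": dict(res_counts),
        "foldback": k_foldback,
        "other": n - k_foldback,
    }


def two_by_two(spec1: dict, spec2: dict, key: str = "foldback") -> list[list[int]]:
    """2x2 table [[k1, n1-k1], [k2, n2-k2]] for a Fisher comparison."""
    return [
        [spec1[key], spec1["n"] - spec1[key]],
        [spec2[key], spec2["n"] - spec2[key]],
    ]
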