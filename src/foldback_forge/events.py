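"""Apply GCR events to a toy genome and record ground truth.

The foldback inversion follows the hairpin mechanism: a DSB telomeric of a
hairpin-forming inverted repeat is resected 5'->3', the exposed ssDNA folds
back at the site, the 3' flap beyond the telomeric arm is cleaved, and
extension of the annealed hairpin copies the chromosome in inverted
orientation from the site out to a resolution breakpoint.  The resulting
product, read from the surviving telomere, is::

    [secondary segment] + revcomp(ref[arm2_end : d]) + ref[arm1_start : L]

where ``d`` is the resolution breakpoint fixed by the secondary
rearrangement: de novo telomere addition, single-strand annealing (SSA)
capture of the fragment beyond an inverted homology pair (captured copy
number 1), or a homology-mediated translocation that duplicates a donor
chromosome's telomeric segment (copy number 2).

Junction convention used package-wide: an inversion junction is reported as
``(pos_a, pos_b)`` = the *inner* ends of the two hairpin arms (pos_a =
arm1 end, pos_b = arm2 start), i.e. the loop boundaries, with junction
microhomology (= the stem) assigned maximally to the inverted side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from ._seq import revcomp
from .genome import (
    Feature,
    LiteralSegment,
    RefSegment,
    ToyGenome,
    assemble_product,
)
from .hairpin import HairpinSite

EventType = Literal[
    "foldback_inversion",
    "telomere_addition",
    "mh_translocation",
    "interstitial_deletion",
]

SecondaryResolution = Literal[
    "ssa_capture", "homology_translocation", "telomere_addition", "none"
]

#: tandem telomere-unit copies appended by de novo telomere addition;
#: the downstream detection threshold is 12 copies
TELOMERE_ADDITION_COPIES = 25
TELOMERE_DETECTION_MIN_COPIES = 12


@dataclass
class GCREventTruth:
    """Ground truth for one simulated GCR event."""

    event_type: EventType
    chromosome: str
    hairpin_site: HairpinSite | None = None
    resection_start: int | None = None
    #: (pos_a, pos_b, strand_a, strand_b) on the reference; for foldbacks the
    #: inner arm ends with strands ('-', '+') (inverted copy joins plus strand)
    inversion_junction: tuple[int, int, str, str] | None = None
    secondary_resolution: SecondaryResolution = "none"
    #: reference breakpoints of the secondary junction, when one exists:
    #: ((chromA, posA, strandA), (chromB, posB, strandB))
    secondary_junction: tuple | None = None
    microhomology_len: int = 0
    #: primary junction breakpoints for simple (non-foldback) events
    breakpoints: tuple | None = None
    product_chromosome: str = "chr1"
    flap_len: int = 0

    def validate(self) -> None:
        if self.event_type == "foldback_inversion":
            if self.hairpin_site is None or self.inversion_junction is None:
                raise ValueError("foldback truth requires a site and a junction")
        if self.microhomology_len < 0:
            raise ValueError("microhomology_len must be >= 0")


def apply_foldback_inversion(
    genome: ToyGenome,
    site: HairpinSite,
    resection_start: int,
    flap_len: int = 0,
    secondary: SecondaryResolution = "telomere_addition",
    resolution_breakpoint: int | None = None,
    telomere_unit: str = "TGTGGG",
) -> tuple[ToyGenome, GCREventTruth]:
    """Apply a hairpin-mediated foldback inversion with a secondary resolution.

    ``resection_start`` (the initiating break) must be telomeric of the
    site; everything telomeric of it — including the counter-selected
    cassette — is lost.  ``resolution_breakpoint`` fixes how far the
    inverted copy extends; it defaults per secondary (the inner edge of the
    homology / repeat target, or site end + 1200 for telomere addition).
    """
    chrom = site.chromosome or "chr1"
    a1s, a1e = site.arm1
    a2s, a2e = site.arm2
    if not (0 <= resection_start <= a1s):
        raise ValueError("resection_start must be telomeric of the hairpin site")
    if flap_len < 0:
        raise ValueError("flap_len must be >= 0")
    seq = genome.chromosomes[chrom]
    if seq[a1s:a1e] != revcomp(seq[a2s:a2e]):
        raise ValueError("site is not a perfect inverted repeat on this genome")

    L = len(seq)
    segments: list[RefSegment | LiteralSegment]
    secondary_junction = None

    if secondary == "telomere_addition":
        d = resolution_breakpoint if resolution_breakpoint is not None else a2e + 1200
        tel = telomere_unit * TELOMERE_ADDITION_COPIES
        segments = [
            LiteralSegment(tel, kind="telomere_seed", name="de_novo_tel"),
            RefSegment(chrom, a2e, d, "-"),
            RefSegment(chrom, a1s, L, "+"),
        ]
        secondary_junction = ((None, None, None), (chrom, d, "-"))
    elif secondary == "ssa_capture":
        h1, h2 = _inverted_pair(genome, kind="homology_block", chrom=chrom)
        if h1.end > resection_start:
            raise ValueError("telomeric homology copy must be on the lost fragment")
        d = h2.start
        segments = [
            RefSegment(chrom, 0, h1.end, "+"),
            RefSegment(chrom, a2e, d, "-"),
            RefSegment(chrom, a1s, L, "+"),
        ]
        secondary_junction = ((chrom, h1.end, "+"), (chrom, h2.start, "-"))
    elif secondary == "homology_translocation":
        r1, r2 = _inverted_pair(genome, kind="repeat_element", chrom=chrom)
        d = r1.end
        donor = r2.chromosome
        segments = [
            RefSegment(donor, 0, r2.start, "+"),
            RefSegment(chrom, a2e, d, "-"),
            RefSegment(chrom, a1s, L, "+"),
        ]
        secondary_junction = ((donor, r2.end, "+"), (chrom, r1.start, "-"))
    elif secondary == "none":
        d = resolution_breakpoint if resolution_breakpoint is not None else a2e + 1200
        segments = [
            RefSegment(chrom, a2e, d, "-"),
            RefSegment(chrom, a1s, L, "+"),
        ]
    else:
        raise ValueError(f"unknown secondary resolution {secondary!r}")

    if d <= a2e:
        raise ValueError("resolution breakpoint must be centromeric of the site")

    product = assemble_product(genome, chrom, segments)
    truth = GCREventTruth(
        event_type="foldback_inversion",
        chromosome=chrom,
        hairpin_site=site,
        resection_start=resection_start,
        inversion_junction=(a1e, a2s, "-", "+"),
        secondary_resolution=secondary,
        secondary_junction=secondary_junction,
        microhomology_len=site.stem_len,
        product_chromosome=chrom,
        flap_len=flap_len,
    )
    truth.validate()
    if secondary != "none":
        _assert_monocentric(product, chrom)
    return product, truth


def _inverted_pair(genome: ToyGenome, kind: str, chrom: str) -> tuple[Feature, Feature]:
    """The (telomeric/assay-side, target) members of an inverted element pair."""
    feats = genome.features_of(kind)
    pairs: dict[str, list[Feature]] = {}
    for f in feats:
        pairs.setdefault(f.name.rsplit("_", 1)[0], []).append(f)
    for members in pairs.values():
        if len(members) == 2 and any(m.inverted for m in members):
            a, b = sorted(members, key=lambda m: (m.chromosome != chrom, m.start))
            return a, b
    raise ValueError(f"genome has no inverted {kind} pair required for this resolution")


def _assert_monocentric(product: ToyGenome, chrom: str) -> None:
    n = len(product.features_of("centromere", chrom))
    if n != 1:
        raise AssertionError(f"product {chrom} has {n} centromeres")


def apply_simple_gcr(
    genome: ToyGenome,
    kind: EventType,
    breakpoint: int,
    mh_len: int = 0,
    chrom: str = "chr1",
    donor_chrom: str | None = None,
    deletion_start: int | None = None,
    telomere_unit: str = "TGTGGG",
) -> tuple[ToyGenome, GCREventTruth]:
    """Apply a non-foldback GCR: telomere addition, microhomology-mediated
    translocation, or interstitial deletion.

    The breakpoint is the centromeric junction end.  The telomeric side
    (which carries the counter-selected cassette) is lost for telomere
    addition and translocation; an interstitial deletion removes
    ``[deletion_start, breakpoint)`` internally instead, keeping both
    native telomeres.  For events with ``mh_len`` > 0 the join is placed
    across ``mh_len`` identical bases that must already be present in the
    two reference contexts (searched; error when no shared context exists).
    """
    seq = genome.chromosomes[chrom]
    L = len(seq)
    b = int(breakpoint)

    if kind == "telomere_addition":
        tel = telomere_unit * TELOMERE_ADDITION_COPIES
        segments = [
            LiteralSegment(tel, kind="telomere_seed", name="de_novo_tel"),
            RefSegment(chrom, b, L, "+"),
        ]
        product = assemble_product(genome, chrom, segments)
        truth = GCREventTruth(
            event_type="telomere_addition",
            chromosome=chrom,
            breakpoints=((None, None, None), (chrom, b, "+")),
            microhomology_len=0,
            product_chromosome=chrom,
        )
    elif kind == "mh_translocation":
        if donor_chrom is None:
            donor_chrom = next(c for c in genome.chromosomes if c != chrom)
        t = _find_shared_context(
            genome.chromosomes[donor_chrom], seq, b, mh_len,
            avoid=genome.features_of("telomere_seed", donor_chrom),
        )
        segments = [
            RefSegment(donor_chrom, 0, t, "+"),
            RefSegment(chrom, b, L, "+"),
        ]
        product = assemble_product(genome, chrom, segments)
        truth = GCREventTruth(
            event_type="mh_translocation",
            chromosome=chrom,
            breakpoints=((donor_chrom, t, "+"), (chrom, b, "+")),
            microhomology_len=mh_len,
            product_chromosome=chrom,
        )
    elif kind == "interstitial_deletion":
        if deletion_start is None:
            raise ValueError("interstitial_deletion requires deletion_start")
        s, e = int(deletion_start), b
        if not (0 < s < e < L):
            raise ValueError("deletion interval must be internal")
        if mh_len > 0 and seq[s - mh_len : s] != seq[e - mh_len : e]:
            raise ValueError(
                f"no {mh_len}-base shared context at the requested deletion ends"
            )
        segments = [
            RefSegment(chrom, 0, s, "+"),
            RefSegment(chrom, e, L, "+"),
        ]
        product = assemble_product(genome, chrom, segments)
        truth = GCREventTruth(
            event_type="interstitial_deletion",
            chromosome=chrom,
            breakpoints=((chrom, s, "+"), (chrom, e, "+")),
            microhomology_len=mh_len,
            product_chromosome=chrom,
        )
    else:
        raise ValueError(f"unknown simple GCR kind {kind!r}")

    truth.validate()
    _assert_monocentric(product, chrom)
    return product, truth


def _find_shared_context(
    donor: str, seq: str, b: int, mh_len: int, avoid: list[Feature] | None = None
) -> int:
    """Donor position t with exactly ``mh_len`` shared bases before the join.

    Requires donor[t-mh:t] == seq[b-mh:b] and mismatch one base further out,
    so the measured junction microhomology is exactly ``mh_len``.
    """
    avoid = avoid or []
    margin = 200  # keep the join clear of donor ends
    for t in range(margin, len(donor) - margin):
        if any(f.start - margin < t < f.end + margin for f in avoid):
            continue
        if mh_len > 0 and donor[t - mh_len : t] != seq[b - mh_len : b]:
            continue
        if donor[t - mh_len - 1] == seq[b - mh_len - 1]:
            continue  # context longer than requested
        if donor[t] == seq[b]:
            continue  # join would carry forward homology
        return t
    raise ValueError(
        f"no {mh_len}-base shared context constructible on the donor chromosome"
    )


def find_deletion_end(
    seq: str, start: int, mh_len: int, min_len: int, max_len: int
) -> int:
    """Smallest deletion end e in [start+min_len, start+max_len] whose
    reference context shares exactly ``mh_len`` bases with ``start``'s."""
    for e in range(start + min_len, min(start + max_len, len(seq) - 200)):
        if mh_len > 0 and seq[e - mh_len : e] != seq[start - mh_len : start]:
            continue
        if seq[e - mh_len - 1] == seq[start - mh_len - 1]:
            continue
        if seq[e] == seq[start]:
            continue
        return e
    raise ValueError(f"no deletion end with a {mh_len}-base shared context found")
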