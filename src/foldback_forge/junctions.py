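"""Junction-defining discordant pairs, junction assembly and noise filtering.

A read pair is *discordant* when its mates map to different chromosomes,
in the same orientation (the inversion signature), or with an implied
insert outside mean ± 3 sd.  Discordant pairs whose anchors co-locate
within one insert length are clustered; pairs with one mapped and one
unmapped mate form one-end-anchored clusters (novel-sequence junctions
such as de novo telomere additions).

Each cluster's junction is then sequenced in silico: unmapped reads whose
mates anchor near the cluster are oriented by their anchored mate,
assembled by greedy maximal-overlap consensus (majority base per column),
and the contig is aligned back to the reference from both ends to fix
base-precise breakpoints.  Junction microhomology — reference sequence
assignable to both sides of the join — is reported with the convention
that the side-A alignment keeps its maximal extent and side B is trimmed.

Validation follows a two-criterion rule: enough supporting pairs in
absolute terms, and enough relative to the local span depth per copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._seq import revcomp
from .depth import DepthProfile
from .genome import ToyGenome
from .mapping import AlignmentRecord, is_concordant
from .reads import ReadPair

Geometry = Literal["inversion", "deletion_like", "translocation", "insertion_like"]

DEFAULT_MIN_SUPPORT = 3
#: validated junctions need support >= alpha * local span depth per copy
DEFAULT_SPAN_FRACTION = 0.2
#: minimum exact overlap for contig extension during assembly
MIN_ASSEMBLY_OVERLAP = 15
#: tandem telomere-unit copies required to call a telomeric junction side
TELOMERE_MIN_UNITS = 12


@dataclass
class Anchor:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DiscordantCluster:
    anchor_a: Anchor
    anchor_b: Anchor | None
    n_support_pairs: int
    geometry: Geometry
    one_end: bool = False
    pair_names: list[str] = field(default_factory=list)


@dataclass
class Breakpoint:
    chrom: str
    pos: int
    strand: str


@dataclass
class JunctionCall:
    cluster: DiscordantCluster
    contig: str
    breakpoint_a: Breakpoint | None
    breakpoint_b: Breakpoint | None
    microhomology_len: int
    inserted_bases: str
    coarse: bool = False
    b_is_telomere: bool = False
    n_telomere_units: int = 0
    validated: bool | None = None
    invalid_reason: str | None = None

    @property
    def n_support_pairs(self) -> int:
        return self.cluster.n_support_pairs


def detect_discordant_clusters(
    alignments: Sequence[tuple[AlignmentRecord, AlignmentRecord]],
    insert_mean: float,
    insert_sd: float,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[DiscordantCluster]:
    """Cluster junction-defining discordant pairs (and one-end anchors)."""
    discordant: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    one_end: list[AlignmentRecord] = []
    for a, b in alignments:
        if a.mapped and b.mapped:
            if not (a.unique and b.unique):
                continue
            if not is_concordant(a, b, insert_mean, insert_sd):
                discordant.append((a, b))
        elif a.mapped and a.unique and not b.mapped:
            one_end.append(a)
        elif b.mapped and b.unique and not a.mapped:
            one_end.append(b)

    clusters = _cluster_pairs(discordant, insert_mean, insert_sd)
    oe_clusters = _cluster_one_end(one_end, insert_mean)
    # a one-end cluster adjacent to a paired cluster describes the same
    # junction; keep the richer paired cluster
    kept_oe = []
    for oc in oe_clusters:
        near = False
        for c in clusters:
            for anc in (c.anchor_a, c.anchor_b):
                if (
                    anc is not None
                    and anc.chrom == oc.anchor_a.chrom
                    and abs(anc.start - oc.anchor_a.start) <= 2 * insert_mean
                ):
                    near = True
        if not near:
            kept_oe.append(oc)
    clusters.extend(kept_oe)
    return [c for c in clusters if c.n_support_pairs >= min_support]


def _pair_key(a: AlignmentRecord, b: AlignmentRecord) -> tuple:
    first, second = sorted(
        (a, b), key=lambda r: (r.chrom, r.start)
    )
    return (first.chrom, first.strand, second.chrom, second.strand), first, second


def _geometry(first: AlignmentRecord, second: AlignmentRecord,
              insert_mean: float, insert_sd: float) -> Geometry:
    if first.chrom != second.chrom:
        return "translocation"
    if first.strand == second.strand:
        return "inversion"
    if first.strand == "+" and second.strand == "-":
        insert = second.end - first.start
        if insert > insert_mean + 3 * insert_sd:
            return "deletion_like"
        return "insertion_like"
    return "insertion_like"  # everted (RF) orientation


def _cluster_pairs(
    discordant: list[tuple[AlignmentRecord, AlignmentRecord]],
    insert_mean: float,
    insert_sd: float,
) -> list[DiscordantCluster]:
    groups: dict[tuple, list[tuple[AlignmentRecord, AlignmentRecord]]] = {}
    for a, b in discordant:
        key, first, second = _pair_key(a, b)
        groups.setdefault(key, []).append((first, second))

    clusters: list[DiscordantCluster] = []
    for key, members in groups.items():
        members.sort(key=lambda fs: (fs[0].start, fs[1].start))
        current: list[tuple[AlignmentRecord, AlignmentRecord]] = []
        for fs in members:
            if current and (
                fs[0].start - current[-1][0].start > insert_mean
                or abs(fs[1].start - current[-1][1].start) > insert_mean
            ):
                clusters.append(_finish_cluster(current, insert_mean, insert_sd))
                current = []
            current.append(fs)
        if current:
            clusters.append(_finish_cluster(current, insert_mean, insert_sd))
    return clusters


def _finish_cluster(
    members: list[tuple[AlignmentRecord, AlignmentRecord]],
    insert_mean: float,
    insert_sd: float,
) -> DiscordantCluster:
    firsts = [f for f, _ in members]
    seconds = [s for _, s in members]
    anchor_a = Anchor(
        firsts[0].chrom,
        min(r.start for r in firsts),
        max(r.end for r in firsts),
        firsts[0].strand,
    )
    anchor_b = Anchor(
        seconds[0].chrom,
        min(r.start for r in seconds),
        max(r.end for r in seconds),
        seconds[0].strand,
    )
    geom = _geometry(firsts[0], seconds[0], insert_mean, insert_sd)
    return DiscordantCluster(
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        n_support_pairs=len(members),
        geometry=geom,
        pair_names=[f.read_id for f in firsts],
    )


def _cluster_one_end(
    anchors: list[AlignmentRecord], insert_mean: float
) -> list[DiscordantCluster]:
    clusters: list[DiscordantCluster] = []
    anchors = sorted(anchors, key=lambda r: (r.chrom, r.strand, r.start))
    current: list[AlignmentRecord] = []

    def finish(group: list[AlignmentRecord]) -> None:
        if not group:
            return
        clusters.append(
            DiscordantCluster(
                anchor_a=Anchor(
                    group[0].chrom,
                    min(r.start for r in group),
                    max(r.end for r in group),
                    group[0].strand,
                ),
                anchor_b=None,
                n_support_pairs=len(group),
                geometry="insertion_like",
                one_end=True,
                pair_names=[r.read_id for r in group],
            )
        )

    for rec in anchors:
        if current and (
            rec.chrom != current[-1].chrom
            or rec.strand != current[-1].strand
            or rec.start - current[-1].start > insert_mean
        ):
            finish(current)
            current = []
        current.append(rec)
    finish(current)
    return clusters


# ---------------------------------------------------------------------------
# junction assembly
# ---------------------------------------------------------------------------

def collect_junction_reads(
    cluster: DiscordantCluster,
    alignments: Sequence[tuple[AlignmentRecord, AlignmentRecord]],
    pairs_by_name: dict[str, ReadPair],
    insert_mean: float,
) -> list[str]:
    """Junction-sequencing reads oriented by their anchored mates.

    Reads that failed to map (or mapped ambiguously) but whose mate is
    uniquely anchored within one insert length of a cluster anchor are the
    reads that cross the novel junction.  Each is flipped so that all
    returned sequences share the orientation of the rearranged product:
    a '+' anchored mate implies its partner reads the product's reverse
    strand, so the partner is reverse-complemented, and vice versa.
    """
    margin = int(insert_mean) + 200
    windows = []
    for anc in (cluster.anchor_a, cluster.anchor_b):
        if anc is not None:
            windows.append((anc.chrom, anc.start - margin, anc.end + margin))

    out: list[str] = []
    for a, b in alignments:
        for rec, other in ((a, b), (b, a)):
            if rec.mapped and not (other.mapped and other.unique):
                if not rec.unique:
                    continue
                if not any(
                    rec.chrom == c and lo <= rec.start <= hi for c, lo, hi in windows
                ):
                    continue
                pair = pairs_by_name.get(rec.read_id)
                if pair is None:
                    continue
                raw = pair.seq2 if other.mate == 1 else pair.seq1
                out.append(revcomp(raw) if rec.strand == "+" else raw)
    return sorted(out)


def assemble_contigs(
    reads: list[str], min_overlap: int = MIN_ASSEMBLY_OVERLAP
) -> list[tuple[str, int]]:
    """Greedy overlap assembly into one or more (contig, n_reads) pieces.

    Reads that share no overlap with the growing contig seed a new contig
    on the next round, so reads leaked in from a nearby junction separate
    instead of corrupting the consensus.  Contigs are returned largest
    read-support first.
    """
    contigs: list[tuple[str, int]] = []
    worklist = sorted(reads)
    while worklist:
        contig, used = _assemble_one_indexed(worklist, min_overlap)
        contigs.append((contig, len(used)))
        worklist = [r for i, r in enumerate(worklist) if i not in used]
    contigs.sort(key=lambda c: -c[1])
    return contigs


def assemble_contig(reads: list[str], min_overlap: int = MIN_ASSEMBLY_OVERLAP) -> str:
    """The best-supported contig from greedy overlap assembly."""
    contigs = assemble_contigs(reads, min_overlap)
    return contigs[0][0] if contigs else ""


def _assemble_one_indexed(reads: list[str], min_overlap: int) -> tuple[str, set[int]]:
    k = min_overlap
    seed_i = max(range(len(reads)), key=lambda i: len(reads[i]))
    seed = reads[seed_i]
    placed: list[tuple[str, int]] = [(seed, 0)]
    used: set[int] = {seed_i}
    unplaced = [i for i in range(len(reads)) if i != seed_i]

    def contig_bounds() -> tuple[int, int]:
        lo = min(off for _, off in placed)
        hi = max(off + len(r) for r, off in placed)
        return lo, hi

    def consensus() -> str:
        lo, hi = contig_bounds()
        L = hi - lo
        counts = np.zeros((L, 5), dtype=np.int32)
        idx = {b: i for i, b in enumerate("ACGTN")}
        for r, off in placed:
            for j, base in enumerate(r):
                counts[off - lo + j, idx.get(base, 4)] += 1
        best = np.argmax(counts, axis=1)
        return "".join("ACGTN"[i] for i in best)

    progress = True
    while unplaced and progress:
        progress = False
        cons = consensus()
        lo, _ = contig_bounds()
        kmer_index: dict[str, list[int]] = {}
        for i in range(len(cons) - k + 1):
            kmer_index.setdefault(cons[i : i + k], []).append(i)
        best_read = None
        best_oriented = ""
        best_offset = 0
        best_score = -1
        for ri in unplaced:
            r = reads[ri]
            # junction reads arrive in mixed orientations; try both
            for oriented in (r, revcomp(r)):
                votes: dict[int, int] = {}
                for i in range(0, len(oriented) - k + 1):
                    for cpos in kmer_index.get(oriented[i : i + k], ()):
                        off = cpos - i
                        votes[off] = votes.get(off, 0) + 1
                for off in votes:
                    o_lo = max(0, off)
                    o_hi = min(len(cons), off + len(oriented))
                    if o_hi - o_lo < min_overlap:
                        continue
                    seg_c = cons[o_lo:o_hi]
                    seg_r = oriented[o_lo - off : o_hi - off]
                    matches = sum(1 for x, y in zip(seg_c, seg_r) if x == y)
                    if matches < 0.9 * len(seg_c):
                        continue
                    if matches > best_score:
                        best_score = matches
                        best_read = ri
                        best_oriented = oriented
                        best_offset = off + lo
        if best_read is not None:
            placed.append((best_oriented, best_offset))
            used.add(best_read)
            unplaced.remove(best_read)
            progress = True
    return consensus(), used


def _count_telomere_units(seq: str, unit: str) -> int:
    """Longest tandem run of the telomere unit (either orientation) in seq."""
    best = 0
    for u in (unit, revcomp(unit)):
        for phase in range(len(u)):
            shifted = u[phase:] + u[:phase]
            run = 0
            i = seq.find(shifted)
            while i != -1:
                j = i
                while seq.startswith(shifted, j):
                    j += len(shifted)
                run = max(run, (j - i) // len(shifted))
                i = seq.find(shifted, j + 1)
            best = max(best, run)
    return best


def _telomere_run(seq: str, unit: str, end: Literal["start", "end"]) -> int:
    """Tandem telomere units flush against one end of ``seq`` (any phase
    or orientation); returns the run length in whole units."""
    best = 0
    p = len(unit)
    for u in (unit, revcomp(unit)):
        for phase in range(p):
            rot = u[phase:] + u[:phase]
            i = 0
            if end == "start":
                while seq[i : i + p] == rot:
                    i += p
                best = max(best, i // p)
            else:
                j = len(seq)
                while j - p >= 0 and seq[j - p : j] == rot:
                    j -= p
                best = max(best, (len(seq) - j) // p)
    return best


@dataclass
class _SideMatch:
    chrom: str
    strand: str
    #: contig interval covered by the maximal reference match
    c_lo: int
    c_hi: int
    #: reference coordinate of the junction-adjacent boundary at maximal extent
    ref_boundary: int


def _match_side(
    contig: str, genome: ToyGenome, index, side: Literal["start", "end"]
) -> _SideMatch | None:
    """Maximal exact reference match anchored at one contig end."""
    k = index.k
    n = len(contig)
    if n < k:
        return None
    if side == "start":
        probe_positions = range(0, min(n - k + 1, 80))
    else:
        probe_positions = range(n - k, max(-1, n - k - 80), -1)
    for i in probe_positions:
        kmer = contig[i : i + k]
        hits = list(index.index.get(kmer, ()))
        rc_hits = [(c, p) for c, p in index.index.get(revcomp(kmer), ())]
        candidates = [(c, p, "+") for c, p in hits] + [(c, p, "-") for c, p in rc_hits]
        if not candidates:
            continue
        best = None
        for chrom, p, strand in candidates:
            ref = genome.chromosomes[chrom]
            if strand == "+":
                diag = p - i  # contig[j] == ref[diag + j]
                j_lo, j_hi = i, i + k
                while j_lo > 0 and 0 <= diag + j_lo - 1 and contig[j_lo - 1] == ref[diag + j_lo - 1]:
                    j_lo -= 1
                while j_hi < n and diag + j_hi < len(ref) and contig[j_hi] == ref[diag + j_hi]:
                    j_hi += 1
                boundary = diag + j_hi if side == "start" else diag + j_lo
            else:
                # contig[j] == complement(ref[diag - j])
                diag = p + k - 1 + i  # so that contig[i..i+k) == rc(ref[p..p+k))
                ref_rc_ok = True
                j_lo, j_hi = i, i + k
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                while (
                    j_lo > 0
                    and diag - (j_lo - 1) < len(ref)
                    and contig[j_lo - 1] == comp.get(ref[diag - (j_lo - 1)], "N")
                ):
                    j_lo -= 1
                while (
                    j_hi < n
                    and diag - j_hi >= 0
                    and contig[j_hi] == comp.get(ref[diag - j_hi], "N")
                ):
                    j_hi += 1
                # junction-adjacent boundary (half-open ref coordinate)
                boundary = diag - j_hi + 1 if side == "start" else diag - j_lo + 1
            length = j_hi - j_lo
            cand = (length, chrom, strand, j_lo, j_hi, boundary)
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            continue
        length, chrom, strand, j_lo, j_hi, boundary = best
        # the match must actually reach the contig end it anchors
        if side == "start" and j_lo > 5:
            continue
        if side == "end" and j_hi < n - 5:
            continue
        return _SideMatch(chrom, strand, j_lo, j_hi, boundary)
    return None


def assemble_junction(
    cluster: DiscordantCluster,
    alignments: Sequence[tuple[AlignmentRecord, AlignmentRecord]],
    pairs: Sequence[ReadPair],
    genome: ToyGenome,
    index,
    insert_mean: float,
    telomere_unit: str = "TGTGGG",
) -> JunctionCall:
    """Assemble a cluster's junction and fix base-precise breakpoints.

    The contig is matched against the reference from both ends; the
    contig overlap claimed by both side matches is the junction
    microhomology (assigned to side A: side B's breakpoint is shifted by
    the overlap), and contig sequence claimed by neither side is reported
    as non-templated inserted bases.  When the unanchored side of a
    one-end cluster runs into >= 12 tandem telomere units it is reported
    as a de novo telomere rather than a reference breakpoint.
    """
    pairs_by_name = {p.name: p for p in pairs}
    jreads = collect_junction_reads(cluster, alignments, pairs_by_name, insert_mean)
    contigs = assemble_contigs(jreads)

    # tandem repeats collapse under greedy overlap assembly, so telomere
    # extent is also assessed on the raw junction reads
    read_tel_units = max(
        (
            _telomere_run(r, telomere_unit, end)
            for r in jreads
            for end in ("start", "end")
        ),
        default=0,
    )

    # reads leaked in from a nearby junction assemble into separate contigs;
    # use the best-supported contig whose breakpoints agree with this
    # cluster's own anchors
    for contig, _n_reads in contigs:
        call = _resolve_contig(
            contig, cluster, genome, index, insert_mean, telomere_unit,
            read_tel_units,
        )
        if call is not None:
            return call
    return _coarse_call(cluster, contigs[0][0] if contigs else "")


def _near_anchor(cluster: DiscordantCluster, chrom: str, pos: int, slack: float) -> bool:
    for anc in (cluster.anchor_a, cluster.anchor_b):
        if anc is not None and anc.chrom == chrom:
            if anc.start - slack <= pos <= anc.end + slack:
                return True
    return False


def _resolve_contig(
    contig: str,
    cluster: DiscordantCluster,
    genome: ToyGenome,
    index,
    insert_mean: float,
    telomere_unit: str,
    read_tel_units: int = 0,
) -> JunctionCall | None:
    if len(contig) < 2 * MIN_ASSEMBLY_OVERLAP:
        return None
    slack = insert_mean + 100

    # one junction side made of tandem telomere units is de novo telomere,
    # not reference sequence.  Greedy assembly collapses and can corrupt
    # the repeat phase, so the >= 12 tandem unit detection threshold is
    # assessed on both the contig ends and the raw junction reads; the
    # reference breakpoint comes from whichever contig end matches the
    # reference near the cluster's own anchors.
    tel_start = _telomere_run(contig, telomere_unit, "start")
    tel_end = _telomere_run(contig, telomere_unit, "end")
    tel_evidence = max(tel_start, tel_end, read_tel_units)
    if tel_evidence >= TELOMERE_MIN_UNITS:
        candidates = []
        for side_name in ("start", "end"):
            m = _match_side(contig, genome, index, side_name)
            if m is not None and _near_anchor(cluster, m.chrom, m.ref_boundary, slack):
                candidates.append(m)
        if not candidates:
            return None
        side = max(candidates, key=lambda m: m.c_hi - m.c_lo)
        return JunctionCall(
            cluster=cluster,
            contig=contig,
            breakpoint_a=Breakpoint(side.chrom, side.ref_boundary, side.strand),
            breakpoint_b=None,
            microhomology_len=0,
            inserted_bases="",
            b_is_telomere=True,
            n_telomere_units=tel_evidence,
        )

    a_side = _match_side(contig, genome, index, "start")
    b_side = _match_side(contig, genome, index, "end")
    if a_side is None or b_side is None:
        return None
    if not (
        _near_anchor(cluster, a_side.chrom, a_side.ref_boundary, slack)
        and _near_anchor(cluster, b_side.chrom, b_side.ref_boundary, slack)
    ):
        return None
    if a_side.c_hi >= b_side.c_hi and a_side.c_lo <= b_side.c_lo:
        # one side explains the whole contig; no junction resolvable
        return None
    mh = max(0, a_side.c_hi - b_side.c_lo)
    inserted = contig[a_side.c_hi : b_side.c_lo] if b_side.c_lo > a_side.c_hi else ""
    bp_a = Breakpoint(a_side.chrom, a_side.ref_boundary, a_side.strand)
    # trim side B by the shared overlap (microhomology assigned to side A)
    if b_side.strand == "+":
        bp_b = Breakpoint(b_side.chrom, b_side.ref_boundary + mh, "+")
    else:
        bp_b = Breakpoint(b_side.chrom, b_side.ref_boundary - mh, "-")
    bp_a, bp_b = _canonicalize_inversion(bp_a, bp_b, mh)
    return JunctionCall(
        cluster=cluster,
        contig=contig,
        breakpoint_a=bp_a,
        breakpoint_b=bp_b,
        microhomology_len=mh,
        inserted_bases=inserted,
    )


def _canonicalize_inversion(
    bp_a: Breakpoint, bp_b: Breakpoint, mh: int
) -> tuple[Breakpoint, Breakpoint]:
    """Flip-invariant description of same-chromosome inversion junctions.

    The assembled contig's orientation is arbitrary, so the mh-to-side-A
    rule can land the shared bases on either side.  For an inversion
    junction (one '+' and one '-' side on the same chromosome) the
    canonical form claims the shared overlap for the '-' (inverted) side;
    for a hairpin-mediated foldback this reports the inner arm ends.
    """
    if (
        bp_a.chrom != bp_b.chrom
        or mh <= 0
        or {bp_a.strand, bp_b.strand} != {"+", "-"}
    ):
        return bp_a, bp_b
    minus, plus = (bp_a, bp_b) if bp_a.strand == "-" else (bp_b, bp_a)
    if minus.pos < plus.pos:
        # flipped frame: the physical sides exchange strand roles
        minus, plus = (
            Breakpoint(minus.chrom, plus.pos - mh, "-"),
            Breakpoint(plus.chrom, minus.pos + mh, "+"),
        )
    if bp_a.strand == "-":
        return minus, plus
    return plus, minus


def _coarse_call(cluster: DiscordantCluster, contig: str) -> JunctionCall:
    bp_a = Breakpoint(
        cluster.anchor_a.chrom, cluster.anchor_a.end, cluster.anchor_a.strand
    )
    bp_b = (
        Breakpoint(cluster.anchor_b.chrom, cluster.anchor_b.start, cluster.anchor_b.strand)
        if cluster.anchor_b is not None
        else None
    )
    return JunctionCall(
        cluster=cluster,
        contig=contig,
        breakpoint_a=bp_a,
        breakpoint_b=bp_b,
        microhomology_len=0,
        inserted_bases="",
        coarse=True,
    )


def filter_junctions(
    calls: Sequence[JunctionCall],
    profiles: dict[str, DepthProfile],
    median_depth: float,
    min_support: int = DEFAULT_MIN_SUPPORT,
    span_fraction: float = DEFAULT_SPAN_FRACTION,
) -> list[JunctionCall]:
    """Validate calls against support and local span-depth criteria.

    A call validates iff its supporting pair count is at least
    ``min_support`` and at least ``span_fraction`` of the local span depth
    per copy at each anchor (span depth divided by the local copy number
    estimated from read depth, so duplicated regions are not penalised
    twice).  Failing calls are returned flagged with the failing
    criterion.
    """
    out = []
    for call in calls:
        reason = None
        if call.n_support_pairs < min_support:
            reason = "support"
        else:
            for anc in (call.cluster.anchor_a, call.cluster.anchor_b):
                if anc is None:
                    continue
                prof = profiles[anc.chrom]
                lo = max(0, anc.start)
                hi = min(len(prof.span_depth), max(anc.end, lo + 1))
                span = float(np.median(prof.span_depth[lo:hi]))
                rd = float(np.median(prof.read_depth[lo:hi]))
                copies = max(1.0, round(rd / max(median_depth, 1e-9)))
                if call.n_support_pairs < span_fraction * span / copies:
                    reason = "span_fraction"
                    break
        call.validated = reason is None
        call.invalid_reason = reason
        out.append(call)
    return out


def write_junctions_tsv(path: str | Path, calls: Sequence[JunctionCall]) -> None:
    cols = (
        "chromA\tposA\tstrandA\tchromB\tposB\tstrandB\tsupport\tmh_len\t"
        "inserted\tvalidated\ttelomeric\tjunction_seq\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            ba = c.breakpoint_a
            bb = c.breakpoint_b
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        ba.chrom if ba else ".",
                        ba.pos if ba else ".",
                        ba.strand if ba else ".",
                        bb.chrom if bb else ("telomere" if c.b_is_telomere else "."),
                        bb.pos if bb else ".",
                        bb.strand if bb else ".",
                        c.n_support_pairs,
                        c.microhomology_len,
                        c.inserted_bases or ".",
                        c.validated,
                        c.b_is_telomere,
                        c.contig or ".",
                    )
                )
                + "\n"
            )
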