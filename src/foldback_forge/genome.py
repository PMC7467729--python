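"""Toy assay genomes: construction, feature maps and FASTA/BED output.

A :class:`ToyGenome` is a set of named linear chromosomes plus an annotated
feature map (cassette, homology blocks, telomere seeds, centromeres,
planted hairpin sites, repeat elements).  Coordinates are 0-based
half-open throughout; a reporting helper renders positions relative to a
named anchor feature ("anchor±offset") for human-readable output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._rng import substream
from ._seq import random_dna, revcomp
from .config import SimConfig
from .hairpin import HairpinSite, enumerate_hairpin_sites

FeatureKind = Literal[
    "cassette",
    "homology_block",
    "telomere_seed",
    "centromere",
    "hairpin_site",
    "repeat_element",
]

#: attempts to resample background sequence before giving up
MAX_REJECTION_ATTEMPTS = 1000


@dataclass(frozen=True)
class Feature:
    name: str
    chromosome: str
    start: int
    end: int
    kind: str
    #: set when a feature landed in inverted orientation after a rearrangement
    inverted: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ToyGenome:
    """Named chromosome sequences plus an annotated feature map."""

    chromosomes: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    coordinate_system: str = "0-based half-open"

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        seq = self.chromosomes[chrom]
        return seq[slice(start, end)]

    def features_of(self, kind: str, chrom: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == kind and (chrom is None or f.chromosome == chrom)
        ]

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self) -> None:
        for f in self.features:
            L = len(self.chromosomes[f.chromosome])
            if not (0 <= f.start < f.end <= L):
                raise ValueError(f"feature {f.name} outside {f.chromosome} bounds")
        for chrom in self.chromosomes:
            n_cen = len(self.features_of("centromere", chrom))
            if n_cen != 1:
                raise ValueError(f"{chrom} has {n_cen} centromere features, expected 1")
            tels = self.features_of("telomere_seed", chrom)
            L = len(self.chromosomes[chrom])
            if not any(t.start == 0 for t in tels) or not any(t.end == L for t in tels):
                raise ValueError(f"{chrom} is not telomere-terminated at both ends")

    def anchored_position(self, chrom: str, pos: int, anchor: str) -> str:
        """Render ``pos`` as 'anchor+off' / 'anchor-off' relative to a feature."""
        f = self.feature_by_name(anchor)
        if f.chromosome != chrom:
            raise ValueError(f"anchor {anchor} is on {f.chromosome}, not {chrom}")
        off = pos - f.start
        return f"{anchor}{off:+d}"

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def features_to_bed(self, path: str | Path) -> None:
        """BED with the feature kind in the name column (0-based half-open)."""
        with open(path, "w") as fh:
            for f in sorted(self.features, key=lambda f: (f.chromosome, f.start)):
                fh.write(
                    f"{f.chromosome}\t{f.start}\t{f.end}\t{f.kind}\t0\t"
                    f"{'-' if f.inverted else '+'}\t{f.name}\n"
                )

    @classmethod
    def from_fasta(cls, path: str | Path, bed: str | Path | None = None) -> "ToyGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        chroms = {name: str(fa[name][:]).upper() for name in fa.keys()}
        features: list[Feature] = []
        if bed is not None:
            with open(bed) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    parts = line.rstrip("\n").split("\t")
                    chrom, start, end, kind = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) > 5 else "+"
                    name = parts[6] if len(parts) > 6 else kind
                    features.append(
                        Feature(name, chrom, start, end, kind, inverted=(strand == "-"))
                    )
        return cls(chromosomes=chroms, features=features)


def _complementary(a: str, b: str) -> bool:
    return revcomp(a) == b


class FeatureCollisionError(ValueError):
    """Two requested planted features overlap."""


class RejectionSamplingError(RuntimeError):
    """Background resampling failed to clear the breakpoint region."""


def build_toy_genome(config: SimConfig) -> ToyGenome:
    """Build the annotated assay genome described by ``config``.

    Background sequence is drawn from the seeded "genome" substream.
    Planted hairpin sites are exact inverted repeats.  The background of
    the assay breakpoint region is rejection-sampled until it contains no
    chance inverted repeat with a stem at least as long as the longest
    planted stem (so the planted hotspot is the strongest site there).
    """
    config.validate()
    rng = substream(config.master_seed, "genome")
    names = config.chromosome_names

    planted = _planted_features(config)
    _check_collisions(planted)

    chroms: dict[str, str] = {}
    for name, length in zip(names, config.chromosome_lengths):
        chroms[name] = random_dna(rng, length)

    features: list[Feature] = []
    tel = config.telomere_unit * config.telomere_seed_copies
    for name, frac in zip(names, config.centromere_fractions):
        L = len(chroms[name])
        seq = list(chroms[name])
        seq[: len(tel)] = tel
        seq[L - len(tel) :] = revcomp(tel)
        chroms[name] = "".join(seq)
        features.append(Feature(f"{name}_telL", name, 0, len(tel), "telomere_seed"))
        features.append(Feature(f"{name}_telR", name, L - len(tel), L, "telomere_seed"))
        cen = int(L * frac)
        features.append(Feature(f"{name}_cen", name, cen, cen + 100, "centromere"))

    features.append(
        Feature("cassette", "chr1", *config.cassette_span, "cassette")
    )

    for spec in config.homology_pair_specs + config.repeat_specs:
        elem = random_dna(rng, spec.length)
        second = revcomp(elem) if spec.orientation == "inverted" else elem
        c1, p1 = spec.first
        c2, p2 = spec.second
        chroms[c1] = chroms[c1][:p1] + elem + chroms[c1][p1 + spec.length :]
        chroms[c2] = chroms[c2][:p2] + second + chroms[c2][p2 + spec.length :]
        features.append(Feature(f"{spec.name}_a", c1, p1, p1 + spec.length, spec.kind))
        features.append(
            Feature(
                f"{spec.name}_b", c2, p2, p2 + spec.length, spec.kind,
                inverted=(spec.orientation == "inverted"),
            )
        )

    for i, h in enumerate(config.hairpin_specs):
        arm = random_dna(rng, h.stem_len)
        loop = random_dna(rng, h.loop_len)
        # the stem must not extend inward by chance complementary loop ends
        while _complementary(loop[0], loop[-1]):
            loop = loop[:-1] + random_dna(rng, 1)
        site_seq = arm + loop + revcomp(arm)
        c = h.chromosome
        chroms[c] = (
            chroms[c][: h.position]
            + site_seq
            + chroms[c][h.position + len(site_seq) :]
        )
        # ... nor outward into the flanking background
        end = h.position + len(site_seq)
        while h.position > 0 and _complementary(chroms[c][h.position - 1], chroms[c][end]):
            chroms[c] = (
                chroms[c][: h.position - 1]
                + random_dna(rng, 1)
                + chroms[c][h.position :]
            )
        features.append(
            Feature(
                f"hairpin_{i}", c, h.position, h.position + len(site_seq),
                "hairpin_site",
            )
        )

    genome = ToyGenome(chromosomes=chroms, features=features)
    _guard_breakpoint_region(genome, config, rng)
    genome.validate()
    return genome


def _planted_features(config: SimConfig) -> list[tuple[str, int, int, str]]:
    tel_len = len(config.telomere_unit) * config.telomere_seed_copies
    out: list[tuple[str, int, int, str]] = []
    for name, length, frac in zip(
        config.chromosome_names, config.chromosome_lengths, config.centromere_fractions
    ):
        out.append((name, 0, tel_len, f"{name}_telL"))
        out.append((name, length - tel_len, length, f"{name}_telR"))
        cen = int(length * frac)
        out.append((name, cen, cen + 100, f"{name}_cen"))
    out.append(("chr1", *config.cassette_span, "cassette"))
    for spec in config.homology_pair_specs + config.repeat_specs:
        for tag, (c, p) in (("a", spec.first), ("b", spec.second)):
            out.append((c, p, p + spec.length, f"{spec.name}_{tag}"))
    for i, h in enumerate(config.hairpin_specs):
        out.append(
            (h.chromosome, h.position, h.position + 2 * h.stem_len + h.loop_len,
             f"hairpin_{i}")
        )
    return out


def _check_collisions(planted: list[tuple[str, int, int, str]]) -> None:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in planted:
        by_chrom.setdefault(chrom, []).append((start, end, name))
    collisions = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                collisions.append(f"{chrom}: {n1} [{s1},{e1}) overlaps {n2} [{s2},{e2})")
    if collisions:
        raise FeatureCollisionError(
            "requested planted features collide:\n" + "\n".join(collisions)
        )


def _guard_breakpoint_region(
    genome: ToyGenome, config: SimConfig, rng: np.random.Generator
) -> None:
    """Resample breakpoint-region background until no chance site competes."""
    if not config.hairpin_specs:
        return
    max_stem = max(h.stem_len for h in config.hairpin_specs)
    b0, b1 = config.breakpoint_region
    planted_spans = [
        (f.start, f.end) for f in genome.features_of("hairpin_site", "chr1")
    ]
    protected = [
        (f.start, f.end)
        for f in genome.features
        if f.chromosome == "chr1" and f.start < b1 and b0 < f.end
    ]
    for attempt in range(MAX_REJECTION_ATTEMPTS):
        region = genome.chromosomes["chr1"][b0:b1]
        sites = enumerate_hairpin_sites(region, min_stem=max_stem)
        bad = [
            s
            for s in sites
            if not any(
                ps <= s.span[0] + b0 and s.span[1] + b0 <= pe
                for ps, pe in planted_spans
            )
        ]
        if not bad:
            return
        # resample only unprotected (background) bases inside the region
        seq = list(genome.chromosomes["chr1"])
        for s in bad:
            for pos in range(s.span[0] + b0, s.span[1] + b0):
                if any(ps <= pos < pe for ps, pe in protected):
                    continue
                seq[pos] = "ACGT"[rng.integers(0, 4)]
        genome.chromosomes["chr1"] = "".join(seq)
    raise RejectionSamplingError(
        f"breakpoint region still contains chance inverted repeats with stem >= "
        f"{max_stem} after {MAX_REJECTION_ATTEMPTS} attempts; adjust the planted "
        f"stem lengths or the guarded region"
    )


def planted_hairpin_sites(genome: ToyGenome, config: SimConfig) -> list[HairpinSite]:
    """The planted hairpin features as HairpinSite objects (by construction)."""
    sites = []
    for i, h in enumerate(config.hairpin_specs):
        a1 = (h.position, h.position + h.stem_len)
        a2 = (h.position + h.stem_len + h.loop_len,
              h.position + 2 * h.stem_len + h.loop_len)
        sites.append(
            HairpinSite(
                arm1=a1, arm2=a2, stem_len=h.stem_len, loop_len=h.loop_len,
                perfect_stem=True, chromosome=h.chromosome,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# segment-based product construction (used by the event simulators)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefSegment:
    """A slice of a source chromosome, possibly inverted."""

    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"


@dataclass(frozen=True)
class LiteralSegment:
    """Novel sequence (for example de novo telomere repeats)."""

    seq: str
    kind: str | None = None
    name: str = "novel"


def assemble_product(
    genome: ToyGenome,
    target_chrom: str,
    segments: Sequence[RefSegment | LiteralSegment],
) -> ToyGenome:
    """Rebuild ``target_chrom`` from ordered segments, remapping features.

    Features overlapping a reference segment are clipped to the overlap and
    carried over (orientation-flipped for '-' segments); literal segments
    with a ``kind`` gain a new feature.  Other chromosomes pass through
    untouched.
    """
    parts: list[str] = []
    new_features: list[Feature] = []
    offset = 0
    for si, seg in enumerate(segments):
        if isinstance(seg, LiteralSegment):
            parts.append(seg.seq)
            if seg.kind is not None:
                new_features.append(
                    Feature(seg.name, target_chrom, offset, offset + len(seg.seq),
                            seg.kind)
                )
            offset += len(seg.seq)
            continue
        src = genome.chromosomes[seg.chrom][seg.start : seg.end]
        if seg.strand == "-":
            src = revcomp(src)
        parts.append(src)
        for f in genome.features:
            if f.chromosome != seg.chrom:
                continue
            lo, hi = max(f.start, seg.start), min(f.end, seg.end)
            if lo >= hi:
                continue
            if seg.strand == "+":
                ns, ne = offset + (lo - seg.start), offset + (hi - seg.start)
                inv = f.inverted
            else:
                ns, ne = offset + (seg.end - hi), offset + (seg.end - lo)
                inv = not f.inverted
            new_features.append(
                Feature(f"{f.name}_s{si}", target_chrom, ns, ne, f.kind, inverted=inv)
            )
        offset += seg.end - seg.start

    chroms = dict(genome.chromosomes)
    chroms[target_chrom] = "".join(parts)
    features = [f for f in genome.features if f.chromosome != target_chrom]
    features.extend(new_features)
    return ToyGenome(chromosomes=chroms, features=features)
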