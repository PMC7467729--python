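"""Simulation configuration for the toy GCR assay genome.

The default configuration emulates the geometry of a telomere-proximal
counter-selection GCR assay: a small linear "assay" chromosome whose left
arm carries, from the telomere inward, an inverted homology block (the
ura3-52/URA3 mimic), a counter-selected cassette, and a breakpoint region
in which hairpin-forming inverted repeats are planted — dominated by a
15 bp stem / 3 nt loop hotspot — followed by a repeat element with a
second, inverted copy on a donor chromosome (the Ty/delta mimic).
All coordinates are 0-based half-open, increasing from the left telomere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal


@dataclass(frozen=True)
class PairedElementSpec:
    """Two planted copies of one sequence element (homology or repeat).

    ``orientation`` is "direct" when both copies carry the same sequence and
    "inverted" when the second copy is the reverse complement of the first.
    """

    kind: Literal["homology_block", "repeat_element"]
    length: int
    orientation: Literal["direct", "inverted"]
    first: tuple[str, int]
    second: tuple[str, int]
    name: str = "pair"


@dataclass(frozen=True)
class HairpinSpec:
    """A planted perfect inverted repeat: arm + loop + revcomp(arm).

    ``position`` is the start of the telomeric arm; the site occupies
    ``[position, position + 2*stem_len + loop_len)``.
    """

    chromosome: str
    position: int
    stem_len: int
    loop_len: int


@dataclass
class SimConfig:
    """All knobs of the synthetic assay genome and read simulation."""

    master_seed: int = 0
    n_chromosomes: int = 2
    chromosome_lengths: tuple[int, ...] = (12000, 8000)
    #: counter-selected cassette interval on chromosome 1
    cassette_span: tuple[int, int] = (1500, 2500)
    #: region guarded against chance inverted repeats; GCR breakpoints fall here
    breakpoint_region: tuple[int, int] = (2500, 5300)
    homology_pair_specs: tuple[PairedElementSpec, ...] = (
        PairedElementSpec(
            kind="homology_block",
            length=80,
            orientation="inverted",
            first=("chr1", 600),
            second=("chr1", 5400),
            name="ura3_like",
        ),
    )
    repeat_specs: tuple[PairedElementSpec, ...] = (
        PairedElementSpec(
            kind="repeat_element",
            length=80,
            orientation="inverted",
            first=("chr1", 6200),
            second=("chr2", 3000),
            name="ty_like",
        ),
    )
    hairpin_specs: tuple[HairpinSpec, ...] = (
        HairpinSpec("chr1", 4000, 15, 3),   # the inversion hotspot
        HairpinSpec("chr1", 3400, 6, 3),
        HairpinSpec("chr1", 4600, 5, 20),   # a large-loop site
    )
    centromere_fractions: tuple[float, ...] = (0.66, 0.6)
    telomere_unit: str = "TGTGGG"
    telomere_seed_copies: int = 5
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    coverage: float = 30.0
    error_rate: float = 0.002

    def validate(self) -> None:
        if self.n_chromosomes != len(self.chromosome_lengths):
            raise ValueError("n_chromosomes must match chromosome_lengths")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        c0, c1 = self.cassette_span
        if not (0 <= c0 < c1 <= self.chromosome_lengths[0]):
            raise ValueError("cassette_span must lie within chromosome 1")
        b0, b1 = self.breakpoint_region
        if not (0 <= b0 < b1 <= self.chromosome_lengths[0]):
            raise ValueError("breakpoint_region must lie within chromosome 1")
        for h in self.hairpin_specs:
            if h.stem_len < 4:
                raise ValueError("planted hairpin stems must be >= 4 bp")
            if h.loop_len < 3:
                raise ValueError("planted hairpin loops must be >= 3 nt")
        if not (0.0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be below insert_mean")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "homology_pair_specs" in d:
            d["homology_pair_specs"] = tuple(
                _coerce_pair(p) for p in d["homology_pair_specs"]
            )
        if "repeat_specs" in d:
            d["repeat_specs"] = tuple(_coerce_pair(p) for p in d["repeat_specs"])
        if "hairpin_specs" in d:
            d["hairpin_specs"] = tuple(
                h if isinstance(h, HairpinSpec) else HairpinSpec(*_as_tuple(h))
                for h in d["hairpin_specs"]
            )
        for key in ("chromosome_lengths", "cassette_span", "breakpoint_region",
                    "centromere_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls.from_dict(json.loads(text))


def _as_tuple(h) -> tuple:
    if isinstance(h, dict):
        return (h["chromosome"], h["position"], h["stem_len"], h["loop_len"])
    return tuple(h)


def _coerce_pair(p) -> PairedElementSpec:
    if isinstance(p, PairedElementSpec):
        return p
    if isinstance(p, dict):
        p = dict(p)
        p["first"] = tuple(p["first"])
        p["second"] = tuple(p["second"])
        return PairedElementSpec(**p)
    raise TypeError(f"cannot interpret paired element spec {p!r}")
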