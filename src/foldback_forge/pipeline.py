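"""End-to-end orchestration: simulate -> call -> classify -> rates.

One config and one master seed drive a batch of simulated GCR "isolates":
each isolate receives an event drawn from configured proportions, is
resequenced, and runs through the full rearrangement-calling and
classification pipeline against the unrearranged reference.  The run
produces a classified spectrum, loop-size summaries, truth-vs-called
confusion matrix, and (optionally) fluctuation-rate statistics propagated
to a foldback subtype rate.  Stages communicate via plain files in the
run directory; a manifest records config, seed and output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from ._rng import substream
from .classify import (
    GCRClassification,
    classify_gcr,
    classify_resolution,
    spectrum_table,
)
from .config import SimConfig
from .depth import compute_depths, genome_median_depth, segment_copy_number
from .events import (
    GCREventTruth,
    apply_foldback_inversion,
    apply_simple_gcr,
    find_deletion_end,
)
from .fluctuation import (
    FluctuationData,
    estimate_rate,
    simulate_fluctuation_experiment,
)
from .genome import ToyGenome, build_toy_genome, planted_hairpin_sites
from .hairpin import loop_size_summary
from .junctions import (
    assemble_junction,
    detect_discordant_clusters,
    filter_junctions,
)
from .mapping import ReferenceIndex, map_reads
from .reads import simulate_reads
from .stats import bootstrap_proportion_ci, propagate_subtype_rate


@dataclass
class BatchConfig:
    """What events a batch of isolates receives."""

    n_isolates: int = 20
    #: event-type proportions; foldbacks are split over secondaries below
    proportions: dict = field(
        default_factory=lambda: {
            "foldback_inversion": 0.95,
            "telomere_addition": 0.05,
        }
    )
    secondary_proportions: dict = field(
        default_factory=lambda: {
            "telomere_addition": 0.4,
            "ssa_capture": 0.35,
            "homology_translocation": 0.25,
        }
    )
    #: index into the planted hairpin sites or None for hotspot-weighted draw
    fluctuation_m: float = 2.0
    fluctuation_cultures: int = 24
    cells_per_culture: float = 2.0e8


@dataclass
class IsolateResult:
    truth: GCREventTruth
    classification: GCRClassification
    resolution: str | None
    n_validated: int
    breakpoint_error: int | None


def simulate_isolate(
    reference: ToyGenome,
    config: SimConfig,
    event: str,
    secondary: str,
    rng: np.random.Generator,
) -> tuple[ToyGenome, GCREventTruth]:
    """Apply one event of the requested kind at a randomised position."""
    sites = planted_hairpin_sites(reference, config)
    b0, b1 = config.breakpoint_region
    if event == "foldback_inversion":
        # hotspot preference: the longest stem dominates observed foldbacks
        stems = np.array([s.stem_len for s in sites], dtype=float)
        w = stems**2
        site = sites[int(rng.choice(len(sites), p=w / w.sum()))]
        resection = int(rng.integers(b0, site.arm1[0] - 50))
        return apply_foldback_inversion(
            reference,
            site,
            resection_start=resection,
            secondary=secondary,
            telomere_unit=config.telomere_unit,
        )
    if event == "telomere_addition":
        b = int(rng.integers(b0 + 100, b1 - 100))
        return apply_simple_gcr(
            reference, "telomere_addition", b, telomere_unit=config.telomere_unit
        )
    if event == "mh_translocation":
        mh = int(rng.integers(3, 8))
        for _ in range(20):
            b = int(rng.integers(b0 + 100, b1 - 100))
            try:
                return apply_simple_gcr(reference, "mh_translocation", b, mh_len=mh)
            except ValueError:
                continue
        raise RuntimeError("could not place a microhomology translocation")
    if event == "interstitial_deletion":
        mh = int(rng.integers(2, 6))
        seq = reference.chromosomes["chr1"]
        cassette = reference.feature_by_name("cassette")
        for _ in range(20):
            s = int(rng.integers(300, cassette.start - 50))
            try:
                e = find_deletion_end(seq, s, mh, cassette.end - s + 100, b1 - s)
                return apply_simple_gcr(
                    reference, "interstitial_deletion", e, mh_len=mh, deletion_start=s
                )
            except ValueError:
                continue
        raise RuntimeError("could not place an interstitial deletion")
    raise ValueError(f"unknown event type {event!r}")


def call_isolate(
    reference: ToyGenome,
    index: ReferenceIndex,
    product: ToyGenome,
    config: SimConfig,
    rng: np.random.Generator,
):
    """Resequence a product genome and call junctions + segments on it."""
    pairs = simulate_reads(
        product,
        coverage=config.coverage,
        read_length=config.read_length,
        insert_mean=config.insert_mean,
        insert_sd=config.insert_sd,
        error_rate=config.error_rate,
        seed=rng,
    )
    alignments = map_reads(reference, pairs, index=index)
    profiles = compute_depths(alignments, reference, config.insert_mean, config.insert_sd)
    median_depth = genome_median_depth(profiles)
    clusters = detect_discordant_clusters(
        alignments, config.insert_mean, config.insert_sd
    )
    calls = [
        assemble_junction(
            c, alignments, pairs, reference, index, config.insert_mean,
            telomere_unit=config.telomere_unit,
        )
        for c in clusters
    ]
    calls = filter_junctions(calls, profiles, median_depth)
    segments = []
    for chrom, prof in profiles.items():
        segments.extend(segment_copy_number(prof, median_depth))
    return calls, segments, profiles


def _breakpoint_error(truth: GCREventTruth, classification: GCRClassification) -> int | None:
    if truth.event_type != "foldback_inversion":
        return None
    if classification.event_type != "foldback_inversion":
        return None
    j = classification.primary_junction
    t_a, t_b = truth.inversion_junction[:2]
    got = sorted((j.breakpoint_a.pos, j.breakpoint_b.pos))
    want = sorted((t_a, t_b))
    return max(abs(g - w) for g, w in zip(got, want))


def run_end_to_end(
    config: SimConfig,
    batch: BatchConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full simulate -> call -> classify -> stats pipeline.

    Returns the report dict; when ``out_dir`` is given, also writes the
    report, spectrum and manifest there.
    """
    batch = batch or BatchConfig()
    t0 = time.time()
    reference = build_toy_genome(config)
    index = ReferenceIndex(reference)
    rng = substream(config.master_seed, "batch")

    events = list(batch.proportions)
    probs = np.array([batch.proportions[e] for e in events], dtype=float)
    probs /= probs.sum()
    secondaries = list(batch.secondary_proportions)
    sec_probs = np.array(
        [batch.secondary_proportions[s] for s in secondaries], dtype=float
    )
    sec_probs /= sec_probs.sum()

    results: list[IsolateResult] = []
    for i in range(batch.n_isolates):
        event = events[int(rng.choice(len(events), p=probs))]
        secondary = secondaries[int(rng.choice(len(secondaries), p=sec_probs))]
        product, truth = simulate_isolate(reference, config, event, secondary, rng)
        read_rng = substream(config.master_seed, f"reads_{i}")
        calls, segments, _ = call_isolate(reference, index, product, config, read_rng)
        classification = classify_gcr(calls, segments, reference)
        resolution = None
        if classification.event_type == "foldback_inversion":
            resolution = classify_resolution(classification, segments, reference)
        results.append(
            IsolateResult(
                truth=truth,
                classification=classification,
                resolution=resolution,
                n_validated=sum(1 for c in calls if c.validated),
                breakpoint_error=_breakpoint_error(truth, classification),
            )
        )

    if results:
        spectrum = spectrum_table(
            [r.classification for r in results],
            [r.resolution for r in results],
        )
    else:
        spectrum = {
            "n": 0, "event_counts": {}, "loop_class_counts": {},
            "resolution_counts": {}, "foldback": 0, "other": 0,
        }
    confusion: dict[str, dict[str, int]] = {}
    for r in results:
        confusion.setdefault(r.truth.event_type, {})
        confusion[r.truth.event_type][r.classification.event_type] = (
            confusion[r.truth.event_type].get(r.classification.event_type, 0) + 1
        )

    inferences = [
        r.classification.hairpin
        for r in results
        if r.classification.hairpin is not None
    ]
    loop_summary = None
    if inferences:
        per_event = loop_size_summary(inferences, "per_event")
        per_site = loop_size_summary(inferences, "per_site")
        loop_summary = {
            "per_event_median": per_event.median,
            "per_event_counts": {str(k): v for k, v in per_event.counts.items()},
            "per_site_median": per_site.median,
            "per_site_counts": {str(k): v for k, v in per_site.counts.items()},
        }

    counts = simulate_fluctuation_experiment(
        batch.fluctuation_m,
        batch.fluctuation_cultures,
        substream(config.master_seed, "fluctuation"),
    )
    rate = estimate_rate(FluctuationData(tuple(counts), batch.cells_per_culture))
    prop = subtype = None
    if spectrum["n"] > 0:
        prop = bootstrap_proportion_ci(
            spectrum["foldback"], spectrum["n"],
            seed=substream(config.master_seed, "bootstrap"),
        )
        subtype = propagate_subtype_rate(rate, prop)

    n_fold_truth = sum(1 for r in results if r.truth.event_type == "foldback_inversion")
    n_fold_correct = sum(
        1
        for r in results
        if r.truth.event_type == "foldback_inversion"
        and r.classification.event_type == "foldback_inversion"
        and (r.breakpoint_error is not None and r.breakpoint_error <= 5)
    )

    report = {
        "version": __version__,
        "master_seed": config.master_seed,
        "n_isolates": batch.n_isolates,
        "spectrum": spectrum,
        "confusion": confusion,
        "loop_summary": loop_summary,
        "gcr_rate": {
            "m": rate.m, "r": rate.r, "r_lo": rate.r_lo, "r_hi": rate.r_hi,
        },
        "foldback_proportion": None if prop is None else {
            "p": prop.p, "p_lo": prop.p_lo, "p_hi": prop.p_hi,
            "pseudo_applied": prop.pseudo_applied,
        },
        "foldback_rate": None if subtype is None else {
            "q": subtype.q, "q_lo": subtype.q_lo, "q_hi": subtype.q_hi,
        },
        "foldback_recall": (n_fold_correct / n_fold_truth) if n_fold_truth else None,
        "runtime_s": round(time.time() - t0, 2),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        stable = {k: v for k, v in report.items() if k != "runtime_s"}
        report_path.write_text(json.dumps(stable, indent=2, sort_keys=True))
        manifest = RunManifest.create(config, [report_path])
        (out / "manifest.json").write_text(manifest.to_json())
    return report


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    version: str
    digests: dict[str, str]
    timestamp: str

    @classmethod
    def create(cls, config: SimConfig, paths: Sequence[Path]) -> "RunManifest":
        digests = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in paths
        }
        return cls(
            config=json.loads(config.to_json()),
            master_seed=config.master_seed,
            version=__version__,
            digests=digests,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
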