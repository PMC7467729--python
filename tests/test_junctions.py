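"""Discordant-pair clustering, junction assembly and the noise filter."""

import numpy as np
import pytest

from foldback_forge._rng import substream
from foldback_forge.depth import DepthProfile, compute_depths, genome_median_depth
from foldback_forge.events import apply_foldback_inversion, apply_simple_gcr, find_deletion_end
from foldback_forge.junctions import (
    Anchor,
    DiscordantCluster,
    JunctionCall,
    assemble_contig,
    assemble_junction,
    detect_discordant_clusters,
    filter_junctions,
)
from foldback_forge.mapping import map_reads
from foldback_forge.reads import simulate_reads


def run_caller(reference, index, product, seed, coverage=30, error=0.002):
    pairs = simulate_reads(product, coverage, 100, 300, 30, error, substream(seed, "t"))
    alignments = map_reads(reference, pairs, index=index)
    profiles = compute_depths(alignments, reference, 300, 30)
    clusters = detect_discordant_clusters(alignments, 300, 30)
    calls = [
        assemble_junction(c, alignments, pairs, reference, index, 300)
        for c in clusters
    ]
    calls = filter_junctions(calls, profiles, genome_median_depth(profiles))
    return calls


class TestClusters:
    def test_foldback_yields_inversion_cluster_at_planted_junction(
        self, reference, ref_index, planted_sites
    ):
        product, truth = apply_foldback_inversion(
            reference, planted_sites[0], 3000, secondary="telomere_addition"
        )
        pairs = simulate_reads(product, 30, 100, 300, 30, 0.0, substream(1, "c"))
        alignments = map_reads(reference, pairs, index=ref_index)
        clusters = detect_discordant_clusters(alignments, 300, 30)
        inv = [c for c in clusters if c.geometry == "inversion"]
        assert len(inv) >= 1
        t_a, t_b = truth.inversion_junction[:2]
        best = max(inv, key=lambda c: c.n_support_pairs)
        lo = min(best.anchor_a.start, best.anchor_b.start)
        hi = max(best.anchor_a.end, best.anchor_b.end)
        assert lo - 300 <= t_a <= hi + 300 and lo - 300 <= t_b <= hi + 300

    def test_unrearranged_genome_has_no_clusters(self, reference, ref_index):
        pairs = simulate_reads(reference, 30, 100, 300, 30, 0.0, substream(2, "c"))
        alignments = map_reads(reference, pairs, index=ref_index)
        assert detect_discordant_clusters(alignments, 300, 30) == []

    def test_interstitial_deletion_yields_deletion_like_cluster(
        self, reference, ref_index
    ):
        seq = reference.chromosomes["chr1"]
        e = find_deletion_end(seq, 1000, 2, 1700, 4000)
        product, _ = apply_simple_gcr(
            reference, "interstitial_deletion", e, mh_len=2, deletion_start=1000
        )
        pairs = simulate_reads(product, 30, 100, 300, 30, 0.0, substream(3, "c"))
        alignments = map_reads(reference, pairs, index=ref_index)
        clusters = detect_discordant_clusters(alignments, 300, 30)
        assert any(c.geometry == "deletion_like" for c in clusters)


class TestAssembly:
    def test_majority_consensus_takes_most_common_base(self):
        base = "ACGTACGTACGTACGTACGTGCCATTGAC"
        variant = base[:20] + "A" + base[21:]
        contig = assemble_contig([base, base, variant], min_overlap=15)
        assert contig == base

    def test_foldback_breakpoints_base_exact(self, reference, ref_index, planted_sites):
        for si in (0, 1):
            product, truth = apply_foldback_inversion(
                reference, planted_sites[si], 3000, secondary="telomere_addition"
            )
            calls = run_caller(reference, ref_index, product, seed=40 + si)
            inv = [
                c for c in calls
                if c.validated and c.cluster.geometry == "inversion" and not c.coarse
            ]
            assert len(inv) == 1
            got = sorted((inv[0].breakpoint_a.pos, inv[0].breakpoint_b.pos))
            assert got == sorted(truth.inversion_junction[:2])
            # foldback junction microhomology equals the hairpin stem
            assert inv[0].microhomology_len == planted_sites[si].stem_len
            site = planted_sites[si]
            arm = reference.chromosomes["chr1"][site.arm1[0] : site.arm1[1]]
            loop = reference.chromosomes["chr1"][site.arm1[1] : site.arm2[0]]
            from foldback_forge._seq import revcomp

            junction_seq = arm + loop + revcomp(arm)
            # the contig's orientation is arbitrary
            assert junction_seq in inv[0].contig or revcomp(junction_seq) in inv[0].contig

    def test_planted_translocation_microhomology_recovered(self, reference, ref_index):
        product, truth = apply_simple_gcr(reference, "mh_translocation", 3200, mh_len=5)
        calls = run_caller(reference, ref_index, product, seed=44)
        tr = [c for c in calls if c.validated and c.cluster.geometry == "translocation"]
        assert len(tr) == 1
        assert tr[0].microhomology_len == 5
        truth_bps = {(c, p) for c, p, _ in truth.breakpoints}
        called_bps = {
            (bp.chrom, bp.pos) for bp in (tr[0].breakpoint_a, tr[0].breakpoint_b)
        }
        assert called_bps == truth_bps

    def test_telomere_addition_junction_flagged_telomeric(self, reference, ref_index):
        product, truth = apply_simple_gcr(reference, "telomere_addition", 3200)
        calls = run_caller(reference, ref_index, product, seed=45)
        tel = [c for c in calls if c.validated and c.b_is_telomere]
        assert len(tel) == 1
        assert tel[0].n_telomere_units >= 12
        # the reference flank can chance-match a partial telomere unit, so
        # the breakpoint is ambiguous within one unit length
        assert abs(tel[0].breakpoint_a.pos - 3200) <= 6


class TestFilter:
    def make_call(self, support, coarse=False):
        cluster = DiscordantCluster(
            anchor_a=Anchor("c", 100, 300, "+"),
            anchor_b=Anchor("c", 700, 900, "-"),
            n_support_pairs=support,
            geometry="deletion_like",
        )
        return JunctionCall(
            cluster=cluster, contig="A" * 60, breakpoint_a=None, breakpoint_b=None,
            microhomology_len=0, inserted_bases="", coarse=coarse,
        )

    def profiles(self, span, read=30):
        arr_r = np.full(1000, float(read))
        arr_s = np.full(1000, float(span))
        return {"c": DepthProfile("c", arr_r, arr_s)}

    def test_strong_support_validates(self):
        calls = filter_junctions([self.make_call(12)], self.profiles(30), 30)
        assert calls[0].validated

    def test_below_min_support_fails(self):
        calls = filter_junctions([self.make_call(2)], self.profiles(30), 30)
        assert not calls[0].validated
        assert calls[0].invalid_reason == "support"

    def test_low_span_fraction_fails(self):
        calls = filter_junctions([self.make_call(3)], self.profiles(60), 30)
        assert not calls[0].validated
        assert calls[0].invalid_reason == "span_fraction"

    def test_span_fraction_normalised_by_copy_number(self):
        # span 60 in a copy-2 region behaves like span 30 per copy
        profs = {"c": DepthProfile("c", np.full(1000, 60.0), np.full(1000, 60.0))}
        calls = filter_junctions([self.make_call(7)], profs, median_depth=30)
        assert calls[0].validated

    def test_no_false_validated_junctions_on_control(self, reference, ref_index):
        calls = run_caller(reference, ref_index, reference, seed=46)
        assert sum(1 for c in calls if c.validated) == 0
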