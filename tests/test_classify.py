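"""GCR taxonomy and resolution classes from junctions + segments + features."""

import random

import pytest

from foldback_forge._rng import substream
from foldback_forge.classify import (
    classify_gcr,
    classify_resolution,
    measure_microhomology,
    spectrum_table,
    two_by_two,
    GCRClassification,
)
from foldback_forge.events import (
    apply_foldback_inversion,
    apply_simple_gcr,
    find_deletion_end,
)
from foldback_forge.pipeline import call_isolate


def classify_product(reference, ref_index, product, config, seed):
    calls, segments, _ = call_isolate(
        reference, ref_index, product, config, substream(seed, "cl")
    )
    return calls, segments


class TestEventClassification:
    def test_foldback_genome_has_all_four_evidence_items(
        self, reference, ref_index, config, planted_sites
    ):
        product, _ = apply_foldback_inversion(
            reference, planted_sites[0], 3000, secondary="telomere_addition"
        )
        calls, segs = classify_product(reference, ref_index, product, config, 60)
        cls = classify_gcr(calls, segs, reference)
        assert cls.event_type == "foldback_inversion"
        assert len(cls.evidence) == 4
        assert cls.hairpin is not None
        assert cls.loop_class == "short"

    def test_telomere_addition_genome(self, reference, ref_index, config):
        product, _ = apply_simple_gcr(reference, "telomere_addition", 3300)
        calls, segs = classify_product(reference, ref_index, product, config, 61)
        assert classify_gcr(calls, segs, reference).event_type == "telomere_addition"

    def test_mh_translocation_genome(self, reference, ref_index, config):
        product, _ = apply_simple_gcr(reference, "mh_translocation", 3300, mh_len=4)
        calls, segs = classify_product(reference, ref_index, product, config, 62)
        assert classify_gcr(calls, segs, reference).event_type == "mh_translocation"

    def test_interstitial_deletion_genome(self, reference, ref_index, config):
        seq = reference.chromosomes["chr1"]
        e = find_deletion_end(seq, 1000, 2, 1700, 4000)
        product, _ = apply_simple_gcr(
            reference, "interstitial_deletion", e, mh_len=2, deletion_start=1000
        )
        calls, segs = classify_product(reference, ref_index, product, config, 63)
        assert classify_gcr(calls, segs, reference).event_type == "interstitial_deletion"

    def test_unrearranged_genome_is_none(self, reference, ref_index, config):
        calls, segs = classify_product(reference, ref_index, reference, config, 64)
        assert classify_gcr(calls, segs, reference).event_type == "none"

    def test_classification_invariant_under_junction_order(
        self, reference, ref_index, config, planted_sites
    ):
        product, _ = apply_foldback_inversion(
            reference, planted_sites[0], 3000, secondary="ssa_capture"
        )
        calls, segs = classify_product(reference, ref_index, product, config, 65)
        rng = random.Random(0)
        results = set()
        for _ in range(5):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            cls = classify_gcr(shuffled, segs, reference)
            res = classify_resolution(cls, segs, reference)
            results.add((cls.event_type, res))
        assert results == {("foldback_inversion", "class1_ssa_capture")}

    def test_unknown_chromosome_rejected(self, reference, ref_index, config, planted_sites):
        product, _ = apply_foldback_inversion(
            reference, planted_sites[0], 3000, secondary="telomere_addition"
        )
        calls, segs = classify_product(reference, ref_index, product, config, 66)
        for c in calls:
            if c.breakpoint_a is not None:
                c.breakpoint_a.chrom = "chrX"
        with pytest.raises(ValueError, match="unknown chromosome"):
            classify_gcr(calls, segs, reference)


class TestResolution:
    @pytest.mark.parametrize(
        "secondary,expected",
        [
            ("ssa_capture", "class1_ssa_capture"),
            ("homology_translocation", "class2_homology_translocation"),
            ("telomere_addition", "telomere_addition_resolution"),
        ],
    )
    def test_each_resolution_route(
        self, reference, ref_index, config, planted_sites, secondary, expected
    ):
        product, _ = apply_foldback_inversion(
            reference, planted_sites[1], 3000, secondary=secondary
        )
        calls, segs = classify_product(reference, ref_index, product, config, 67)
        cls = classify_gcr(calls, segs, reference)
        assert cls.event_type == "foldback_inversion"
        assert classify_resolution(cls, segs, reference) == expected

    def test_two_extra_junctions_is_class3(self, reference, ref_index, config, planted_sites):
        product, _ = apply_foldback_inversion(
            reference, planted_sites[0], 3000, secondary="telomere_addition"
        )
        calls, segs = classify_product(reference, ref_index, product, config, 68)
        cls = classify_gcr(calls, segs, reference)
        cls.secondary_junctions = cls.secondary_junctions + [
            c for c in calls if c.cluster.geometry == "inversion"
        ][:1] * 2
        assert classify_resolution(cls, segs, reference) == "class3_complex"

    def test_resolution_requires_foldback(self):
        cls = GCRClassification(event_type="telomere_addition")
        with pytest.raises(ValueError, match="foldback"):
            classify_resolution(cls, [], None)


class TestMicrohomology:
    def test_zero_shared_bases(self):
        junction = "A" * 20 + "C" * 20
        assert measure_microhomology(junction, "A" * 20 + "G" * 20, "T" * 20 + "C" * 20) == 0

    def test_planted_five_base_context(self):
        left = "GATTACAGATTACAG"
        mh = "CGCTA"
        right = "TTGGCCAATTGGCCA"
        junction = left + mh + right
        flank_a = left + mh + "AAAAAGGGGG"       # side A reference continues
        flank_b = "CCCCCTTTTT" + mh + right      # side B reference preceded by mh
        # align flank_b to the junction end
        assert measure_microhomology(junction, flank_a, flank_b[-len(junction):]) == 5

    def test_degenerate_identical_flanks_capped(self):
        junction = "ACGTACGTACGTACGTACGT"
        assert measure_microhomology(junction, junction, junction) == 20

    def test_short_flanks_rejected(self):
        with pytest.raises(ValueError, match="15"):
            measure_microhomology("ACGT" * 10, "ACGT", "ACGT" * 10)


class TestSpectrum:
    def test_counts_match_composition(self):
        foldbacks = [
            GCRClassification(
                event_type="foldback_inversion",
                hairpin=_hairpin(3),
                loop_class="short",
            )
            for _ in range(19)
        ]
        other = [GCRClassification(event_type="telomere_addition")]
        spec = spectrum_table(foldbacks + other)
        assert spec["foldback"] == 19
        assert spec["other"] == 1
        assert spec["event_counts"]["foldback_inversion"] == 19
        assert spec["loop_class_counts"] == {"short": 19}

    def test_all_none_spectrum(self):
        spec = spectrum_table([GCRClassification(event_type="none")] * 3)
        assert spec["foldback"] == 0 and spec["n"] == 3

    def test_two_by_two_layout(self):
        s1 = {"foldback": 19, "n": 20}
        s2 = {"foldback": 8, "n": 16}
        assert two_by_two(s1, s2) == [[19, 1], [8, 8]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spectrum_table([])


def _hairpin(loop):
    from foldback_forge.hairpin import HairpinInference

    return HairpinInference(pos_a=0, pos_b=loop, stem_len=6, loop_len=loop)
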