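"""GCR event application: product structure, truth records, invariants."""

import pytest
from Bio.Seq import Seq

from foldback_forge.config import SimConfig
from foldback_forge.events import (
    TELOMERE_ADDITION_COPIES,
    apply_foldback_inversion,
    apply_simple_gcr,
    find_deletion_end,
)
from foldback_forge.genome import Feature, ToyGenome, build_toy_genome
from foldback_forge.hairpin import HairpinSite, infer_hairpin_from_junction


def rc(s: str) -> str:
    """Independent reverse complement via Biopython."""
    return str(Seq(s).reverse_complement())


def tiny_genome():
    """A hand-laid ~2 kb chromosome with one planted 6 bp stem / 3 nt loop."""
    import numpy as np

    rng = np.random.default_rng(42)
    bases = "ACGT"
    seq = list(bases[i] for i in rng.integers(0, 4, 2000))
    tel = "TGTGGG" * 3
    seq[:18] = tel
    seq[-18:] = rc(tel)
    arm = "GATCCA"
    site = arm + "TTG" + rc(arm)
    seq[900 : 900 + len(site)] = site
    # keep the planted stem non-extendable at the outer flank
    seq[899] = next(b for b in "ACGT" if b != rc(seq[915]))
    s = "".join(seq)
    assert s[899] != rc(s[915]) and s[906] != rc(s[908])
    genome = ToyGenome(
        chromosomes={"chr1": s},
        features=[
            Feature("telL", "chr1", 0, 18, "telomere_seed"),
            Feature("telR", "chr1", 1982, 2000, "telomere_seed"),
            Feature("cen", "chr1", 1500, 1550, "centromere"),
            Feature("cassette", "chr1", 200, 400, "cassette"),
            Feature("hp", "chr1", 900, 915, "hairpin_site"),
        ],
    )
    site_obj = HairpinSite(
        arm1=(900, 906), arm2=(909, 915), stem_len=6, loop_len=3,
        chromosome="chr1",
    )
    return genome, site_obj


class TestFoldback:
    def test_product_matches_hand_constructed_string(self):
        genome, site = tiny_genome()
        seq = genome.chromosomes["chr1"]
        product, truth = apply_foldback_inversion(
            genome, site, resection_start=600, secondary="none",
            resolution_breakpoint=1200,
        )
        # independent string surgery: inverted copy of [arm2_end, 1200)
        # followed by the original chromosome from arm1_start on
        expected = rc(seq[915:1200]) + seq[900:]
        assert product.chromosomes["chr1"] == expected
        assert truth.inversion_junction == (906, 909, "-", "+")
        assert truth.microhomology_len == 6

    def test_junction_window_recovers_planted_stem_and_loop(
        self, reference, config, planted_sites
    ):
        for site in planted_sites:
            _, truth = apply_foldback_inversion(
                reference, site, resection_start=3000, secondary="telomere_addition"
            )
            inf = infer_hairpin_from_junction(
                reference.chromosomes["chr1"], truth.inversion_junction[:2]
            )
            assert (inf.stem_len, inf.loop_len) == (site.stem_len, site.loop_len)

    def test_junction_sequence_is_arm_loop_revcomp_arm(self):
        genome, site = tiny_genome()
        product, _ = apply_foldback_inversion(
            genome, site, resection_start=600, secondary="none",
            resolution_breakpoint=1200,
        )
        junction_pos = 1200 - 915  # length of the inverted prefix
        window = product.chromosomes["chr1"][junction_pos : junction_pos + 15]
        assert window == "GATCCA" + "TTG" + rc("GATCCA")

    def test_ssa_capture_keeps_captured_fragment_single_copy(self, reference, config, planted_sites):
        site = planted_sites[0]
        product, truth = apply_foldback_inversion(
            reference, site, resection_start=3000, secondary="ssa_capture"
        )
        h1 = reference.feature_by_name("ura3_like_a")
        captured = reference.chromosomes["chr1"][100 : h1.start]
        joined = "".join(product.chromosomes.values())
        assert joined.count(captured) == 1
        assert truth.secondary_resolution == "ssa_capture"
        # homology content is not duplicated either
        h_seq = reference.chromosomes["chr1"][h1.start : h1.end]
        assert joined.count(h_seq) == 1

    def test_homology_translocation_duplicates_donor_telomeric_segment(
        self, reference, planted_sites
    ):
        site = planted_sites[0]
        product, truth = apply_foldback_inversion(
            reference, site, resection_start=3000, secondary="homology_translocation"
        )
        r2 = reference.feature_by_name("ty_like_b")
        donor_segment = reference.chromosomes["chr2"][100 : r2.start]
        joined = "".join(product.chromosomes.values())
        assert joined.count(donor_segment) == 2
        # the donor chromosome itself is left intact
        assert product.chromosomes["chr2"] == reference.chromosomes["chr2"]

    def test_products_are_monocentric_and_telomere_terminated(
        self, reference, planted_sites
    ):
        for secondary in ("telomere_addition", "ssa_capture", "homology_translocation"):
            product, _ = apply_foldback_inversion(
                reference, planted_sites[1], resection_start=3000, secondary=secondary
            )
            assert len(product.features_of("centromere", "chr1")) == 1
            tels = product.features_of("telomere_seed", "chr1")
            L = len(product.chromosomes["chr1"])
            assert any(t.start == 0 for t in tels)
            assert any(t.end == L for t in tels)

    def test_ssa_without_homology_pair_rejected(self):
        genome, site = tiny_genome()
        with pytest.raises(ValueError, match="inverted homology_block pair"):
            apply_foldback_inversion(genome, site, 600, secondary="ssa_capture")

    def test_non_inverted_repeat_site_rejected(self, reference):
        fake = HairpinSite(arm1=(3000, 3006), arm2=(3009, 3015), stem_len=6,
                           loop_len=3, chromosome="chr1")
        with pytest.raises(ValueError, match="not a perfect inverted repeat"):
            apply_foldback_inversion(reference, fake, 2600)

    def test_resection_must_be_telomeric_of_site(self, reference, planted_sites):
        with pytest.raises(ValueError, match="telomeric"):
            apply_foldback_inversion(reference, planted_sites[0], 5000)


class TestSimpleGCR:
    def test_telomere_addition_appends_repeats(self, reference, config):
        b = 3200
        product, truth = apply_simple_gcr(
            reference, "telomere_addition", b, telomere_unit=config.telomere_unit
        )
        tel = config.telomere_unit * TELOMERE_ADDITION_COPIES
        assert TELOMERE_ADDITION_COPIES >= 12
        assert product.chromosomes["chr1"] == tel + reference.chromosomes["chr1"][b:]
        assert truth.event_type == "telomere_addition"

    def test_translocation_plants_exact_microhomology(self, reference):
        product, truth = apply_simple_gcr(reference, "mh_translocation", 3200, mh_len=5)
        (donor, t, _), (chrom, b, _) = truth.breakpoints
        dseq = reference.chromosomes[donor]
        cseq = reference.chromosomes[chrom]
        assert dseq[t - 5 : t] == cseq[b - 5 : b]
        assert dseq[t - 6 : t] != cseq[b - 6 : b]
        assert product.chromosomes["chr1"] == dseq[:t] + cseq[b:]

    def test_interstitial_deletion_length_arithmetic(self, reference):
        seq = reference.chromosomes["chr1"]
        s = 1000
        e = find_deletion_end(seq, s, mh_len=3, min_len=1700, max_len=4000)
        product, truth = apply_simple_gcr(
            reference, "interstitial_deletion", e, mh_len=3, deletion_start=s
        )
        assert len(product.chromosomes["chr1"]) == len(seq) - (e - s)
        assert seq[s - 3 : s] == seq[e - 3 : e]

    def test_impossible_microhomology_context_rejected(self, reference):
        with pytest.raises(ValueError, match="shared context"):
            apply_simple_gcr(reference, "mh_translocation", 3200, mh_len=14)
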