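"""Hairpin enumeration, junction inference, loop classes and summaries."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldback_forge._seq import revcomp
from foldback_forge.hairpin import (
    HairpinInference,
    HairpinNotFoundError,
    HairpinSite,
    classify_loop,
    enumerate_hairpin_sites,
    infer_hairpin_from_junction,
    loop_size_summary,
    rank_hairpins_near_dsb,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_sites(seq, min_stem, max_loop=49, min_loop=3):
    """Independent oracle: test every (arm1, arm2) interval pair directly."""
    n = len(seq)
    found = []
    for i1 in range(n):
        for stem in range(min_stem, n):
            j1 = i1 + stem
            if j1 > n:
                break
            arm1 = seq[i1:j1]
            for loop in range(min_loop, max_loop + 1):
                i2 = j1 + loop
                j2 = i2 + stem
                if j2 > n:
                    break
                if seq[i2:j2] != revcomp(arm1):
                    continue
                # outward maximality
                if i1 > 0 and j2 < n and seq[i1 - 1] == COMP[seq[j2]]:
                    continue
                # inward maximality (loop could shrink by 2)
                if loop - 2 >= min_loop and seq[j1] == COMP[seq[i2 - 1]]:
                    continue
                found.append(
                    HairpinSite(arm1=(i1, j1), arm2=(i2, j2), stem_len=stem,
                                loop_len=loop)
                )
    # identical dedup rule: longest stem, then smaller loop, then leftmost
    kept = []
    for s in sorted(found, key=lambda h: (-h.stem_len, h.loop_len, h.center)):
        if any(s.span[0] < k.span[1] and k.span[0] < s.span[1] for k in kept):
            continue
        kept.append(s)
    return sorted(kept, key=lambda h: h.center)


def as_tuples(sites):
    return [(s.arm1, s.arm2, s.stem_len, s.loop_len) for s in sites]


class TestEnumerate:
    def test_homopolymer_has_no_sites(self):
        assert enumerate_hairpin_sites("A" * 10, min_stem=4) == []

    def test_single_perfect_site_with_three_nt_loop(self):
        seq = "GGGCATG" + "AAA" + "CATGCCC"
        sites = enumerate_hairpin_sites(seq, min_stem=4)
        assert len(sites) == 1
        assert (sites[0].stem_len, sites[0].loop_len) == (7, 3)
        assert sites[0].arm1 == (0, 7)
        assert sites[0].arm2 == (10, 17)

    def test_planted_hotspot_is_longest_stem_in_region(self, reference, config):
        b0, b1 = config.breakpoint_region
        region = reference.chromosomes["chr1"][b0:b1]
        sites = enumerate_hairpin_sites(region, min_stem=4)
        best = max(sites, key=lambda s: s.stem_len)
        hot = next(h for h in config.hairpin_specs if h.stem_len == 15)
        assert best.stem_len == 15
        assert best.loop_len == 3
        assert best.arm1[0] + b0 == hot.position
        # strictly the longest stem available in the breakpoint region
        others = [s.stem_len for s in sites if s is not best]
        assert all(s < 15 for s in others)

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError, match="position 3"):
            enumerate_hairpin_sites("ACGNACGT", min_stem=2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_random(self, seed):
        rng = random.Random(seed)
        length = rng.randint(20, 200)
        alphabet = "ACGT" if seed % 2 else "AT"
        seq = "".join(rng.choice(alphabet) for _ in range(length))
        assert as_tuples(enumerate_hairpin_sites(seq, 4)) == as_tuples(
            brute_force_sites(seq, 4)
        )

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGT", min_size=10, max_size=120),
        st.integers(min_value=3, max_value=6),
    )
    def test_matches_brute_force_oracle_property(self, seq, min_stem):
        assert as_tuples(enumerate_hairpin_sites(seq, min_stem)) == as_tuples(
            brute_force_sites(seq, min_stem)
        )


class TestInference:
    def make_reference(self, stem, loop, seed=0):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        arm = "".join(bases[i] for i in rng.integers(0, 4, stem))
        lp = "".join(bases[i] for i in rng.integers(0, 4, max(loop, 0)))
        left = "".join(bases[i] for i in rng.integers(0, 4, 60))
        right = "".join(bases[i] for i in rng.integers(0, 4, 60))
        # guard against chance stem extension at the boundaries
        while left and COMP[left[-1]] == (lp + revcomp(arm) + right)[stem + loop]:
            left = left[:-1]
        while loop >= 1 and COMP[lp[0]] == lp[-1]:
            lp = lp[:-1] + bases[int(rng.integers(0, 4))]
        seq = left + arm + lp + revcomp(arm) + right
        pos_a = len(left) + stem          # arm1 inner end
        pos_b = pos_a + loop              # arm2 start
        return seq, pos_a, pos_b

    @pytest.mark.parametrize("stem,loop", [(6, 3), (15, 3), (8, 20), (4, 5)])
    def test_roundtrip_planted_geometry(self, stem, loop):
        seq, pos_a, pos_b = self.make_reference(stem, loop)
        inf = infer_hairpin_from_junction(seq, (pos_a, pos_b))
        assert (inf.stem_len, inf.loop_len) == (stem, loop)
        assert inf.n_mispairs == 0 and not inf.imperfect

    def test_junction_order_insensitive(self):
        seq, pos_a, pos_b = self.make_reference(8, 4)
        a = infer_hairpin_from_junction(seq, (pos_a, pos_b))
        b = infer_hairpin_from_junction(seq, (pos_b, pos_a))
        assert (a.stem_len, a.loop_len) == (b.stem_len, b.loop_len)

    def test_mispair_counted_when_imperfect_allowed(self):
        seq, pos_a, pos_b = self.make_reference(10, 3, seed=3)
        # substitute one base in the middle of the telomeric arm
        i = pos_a - 5
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        mutated = seq[:i] + sub + seq[i + 1 :]
        inf = infer_hairpin_from_junction(mutated, (pos_a, pos_b), allow_imperfect=True)
        assert inf.n_mispairs == 1
        assert inf.imperfect
        assert inf.stem_len == 10

    def test_exact_mode_truncates_at_mispair(self):
        seq, pos_a, pos_b = self.make_reference(10, 3, seed=3)
        i = pos_a - 5
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        mutated = seq[:i] + sub + seq[i + 1 :]
        inf = infer_hairpin_from_junction(mutated, (pos_a, pos_b), allow_imperfect=False)
        assert inf.stem_len == 4  # truncated where the mispair interrupts

    def test_error_when_no_stem(self):
        seq = "A" * 50 + "C" * 50
        with pytest.raises(HairpinNotFoundError):
            infer_hairpin_from_junction(seq, (50, 50))


class TestLoopClass:
    @pytest.mark.parametrize(
        "loop,expected",
        [(3, "short"), (14, "short"), (15, "large"), (36, "large"), (0, "short")],
    )
    def test_threshold(self, loop, expected):
        assert classify_loop(loop) == expected

    def test_monotone_over_range(self):
        classes = [classify_loop(i) for i in range(0, 10_001)]
        flips = sum(1 for a, b in zip(classes, classes[1:]) if a != b)
        assert flips == 1
        assert classes[14] == "short" and classes[15] == "large"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_loop(-1)


def make_inferences(counts, site_offset=0):
    """Expand a {loop: multiplicity} dict into per-event inferences."""
    out = []
    i = 0
    for loop, mult in sorted(counts.items()):
        for _ in range(mult):
            out.append(
                HairpinInference(
                    pos_a=site_offset + i, pos_b=site_offset + i,
                    stem_len=6, loop_len=loop,
                )
            )
            i += 1
    return out


class TestLoopSummary:
    def test_sae2_distribution_median_3nt(self):
        # per-event loop counts of the short-loop mutant spectrum
        infs = make_inferences({3: 16, 4: 1, 5: 1, 8: 1, 10: 1})
        assert loop_size_summary(infs, "per_event").median == 3

    def test_tel1_distribution_median_midpoint(self):
        infs = make_inferences({4: 1, 10: 4, 25: 1, 35: 2, 39: 1, 44: 1})
        assert loop_size_summary(infs, "per_event").median == 17.5

    def test_single_observation(self):
        assert loop_size_summary(make_inferences({5: 1})).median == 5

    def test_per_site_collapses_repeated_sites(self):
        hot = HairpinInference(pos_a=100, pos_b=103, stem_len=15, loop_len=3)
        others = make_inferences({25: 2}, site_offset=500)
        summary_event = loop_size_summary([hot] * 10 + others, "per_event")
        summary_site = loop_size_summary([hot] * 10 + others, "per_site")
        assert summary_event.n == 12
        assert summary_site.n == 3
        for loop, c in summary_site.counts.items():
            assert c <= summary_event.counts[loop]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            loop_size_summary([])

    def test_cumulative_curve_reaches_one(self):
        s = loop_size_summary(make_inferences({3: 2, 20: 2}))
        assert s.cumulative[-1][1] == pytest.approx(1.0)
        assert s.cumulative[0] == (3, 0.5)


class TestRanking:
    def site(self, center, stem, loop=3):
        half = stem + (loop + 1) // 2
        a1 = (center - half, center - half + stem)
        a2 = (a1[1] + loop, a1[1] + loop + stem)
        return HairpinSite(arm1=a1, arm2=a2, stem_len=stem, loop_len=loop)

    def test_near_site_precedes_stronger_far_site(self):
        near = self.site(1010, 6)
        far = self.site(3000, 15)
        ranked = rank_hairpins_near_dsb([far, near], dsb_pos=1000, window=50)
        assert ranked == [near, far]

    def test_equidistant_sites_ranked_by_stem(self):
        s9 = self.site(1030, 9)
        s6 = self.site(970 - 6, 6)  # roughly mirrored distance
        ranked = rank_hairpins_near_dsb([s6, s9], dsb_pos=1000, window=50)
        assert ranked[0].stem_len == 9

    def test_empty_input(self):
        assert rank_hairpins_near_dsb([], 100) == []
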