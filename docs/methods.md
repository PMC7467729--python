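# Methods

This note documents the models behind `foldback-forge`, the conventions
that every module shares, the parameters that matter, and the limits of
what the synthetic benchmark can show about real data.

## The generative model

### Assay genome

The simulator builds a small linear genome mimicking the geometry of a
telomere-proximal counter-selection GCR assay. Chromosome 1 (default
12 kb), read left to right from the telomere that is lost during GCR
formation, carries:

* a telomere seed (5 tandem copies of the 6-mer unit `TGTGGG`) at each
  end and one centromere feature;
* an 80 bp homology block ("ura3-52/URA3 mimic") between the left
  telomere and the cassette, with an inverted second copy centromeric of
  the breakpoint region — the SSA substrate;
* the counter-selected cassette (default 1.5–2.5 kb), whose loss defines
  a GCR;
* a breakpoint region (2.5–5.3 kb) with planted hairpin sites: by default
  the 15 bp stem / 3 nt loop hotspot, a 6 bp / 3 nt minor site, and a
  5 bp stem / 20 nt large-loop site;
* an 80 bp repeat element ("Ty/delta mimic") whose inverted partner sits
  on donor chromosome 2 (default 8 kb) — the translocation substrate.

Planted hairpin sites are exact inverted repeats (arm + loop +
reverse-complement arm). Construction enforces that a planted stem can be
extended neither outward into the flanking background nor inward into the
loop, so the planted geometry is exactly what enumeration and junction
inference recover. Background sequence in the breakpoint region is
rejection-sampled until it contains no chance inverted repeat with a stem
at least as long as the longest planted stem, making the hotspot the
strongest hairpin in the region by construction.

Paired elements are kept shorter than the read length (80 bp vs 100 bp)
so that every read overlaps unique flanking sequence and maps uniquely;
this is a deliberate simplification — real Ty/delta elements are longer
than reads and produce mapping ambiguity that this benchmark does not
exercise. A dedicated unit fixture with a 500 bp duplicated block covers
the non-unique mapping path instead.

### Events

A foldback inversion is applied as: break at `resection_start` (telomeric
of the hairpin site; everything telomeric of it, including the cassette,
is lost), hairpin formation at the site, 3' flap cleavage, and inverted
extension from the arm out to a resolution breakpoint `d`. The product,
read from the surviving telomere, is

```
[secondary segment] + revcomp(ref[arm2_end : d]) + ref[arm1_start : L]
```

with the secondary segment and `d` fixed by the resolution route:

* **de novo telomere addition** — 25 telomere units (the downstream
  detection threshold is 12), `d` defaulting to site end + 1200 bp;
* **SSA capture** — the fragment up to the telomeric homology copy,
  merged across one homology copy (`d` = inner edge of the centromeric
  copy); the captured fragment and the homology content appear exactly
  once;
* **homology translocation** — the donor chromosome's telomeric segment
  up to its repeat copy (`d` = outer edge of the assay-side repeat); the
  donor is left intact, so its telomeric segment is duplicated.

Simple GCRs (de novo telomere addition, microhomology-mediated
translocation, interstitial deletion) are constructed analogously;
microhomology joins are planted by searching the references for a context
sharing exactly the requested number of bases, so measured junction
microhomology equals the planted value.

Feature maps are carried through every rearrangement (clipped, offset and
orientation-flipped per segment), so products can be asserted monocentric
and telomere-terminated.

### Reads

FR-oriented pairs with uniform fragment starts, Gaussian fragment lengths
(default 300 ± 30 bp), 100 bp reads, 30× coverage and independent
substitution errors at 0.2% per base — deliberately simple: no base
qualities, no indels, no GC bias. Read names encode the true origin for
truth-based scoring.

## Junction conventions

All coordinates are 0-based half-open. A junction is a pair of reference
breakpoints with strands; microhomology — junction bases claimable by both
reference flanks — is assigned maximally to side A, with side B trimmed by
the overlap. Because an assembled contig's orientation is arbitrary, the
description of a same-chromosome inversion junction is canonicalised by
claiming the shared bases for the inverted (`-`) side. Under this
convention a hairpin-mediated foldback junction is reported as the
hairpin's *inner* arm ends `(arm1_end, arm2_start)` with microhomology
equal to the stem length — which makes `infer_hairpin_from_junction`
exact: the gap between the two junction coordinates is the loop, and the
maximal complementary extension outward is the stem.

Hairpin enumeration reports maximal perfect inverted repeats with stem ≥
`min_stem` and loop in [3, 49] nt: neither arm may extend outward, nor
inward while the loop stays ≥ 3 nt. Overlapping candidates are
deduplicated keeping the longest stem, then the smaller loop, then the
leftmost center — mirroring the dominance of the longest-stem hotspot.
Imperfect stems are scored by local alignment (match +1, mispair −1, gap
−2, minimum score 4 — the shortest stem treated as interpretable);
thermodynamic folding is out of scope, so mispair/unpaired counts stand in
for free energy.

Loop classes split at 15 nt (`short` < 15 ≤ `large`). Medians use the
midpoint-of-the-two-central-order-statistics convention for even n.
Loop-size summaries are computed both per event (every rearrangement
counted) and per site (identical junction coordinates collapsed).

## The caller

* **Mapping** — exact 21-mer anchors (stride 7, both strands) plus
  full-length ungapped scoring; reads above 10% mismatches are unmapped.
  Reads spanning a novel junction therefore fail to map and become the
  junction-sequencing reads, reproducing the anchored-pair signal
  structure; ties at the best score are flagged non-unique and excluded
  from depth profiles.
* **Depths** — read depth from uniquely mapped reads; span depth adds the
  inter-mate gap of uniquely mapped concordant pairs (FR, insert within
  mean ± 3 sd), so span ≥ read everywhere.
* **Clusters** — discordant pairs (different chromosomes, same-strand
  orientation, or insert outside mean ± 3 sd) are grouped by anchor
  signature and chained within one insert length; pairs with one unique
  and one unmapped mate form one-end-anchored clusters (suppressed when a
  paired cluster already explains the junction). Clusters need ≥ 3
  supporting pairs.
* **Assembly** — junction reads are oriented by their anchored mates and
  assembled greedily by maximal overlap (≥ 15 bp, ≥ 90% identity, both
  orientations tried) with per-column majority consensus. Reads leaked in
  from a nearby junction (collection windows are one insert wide)
  assemble into separate contigs; a contig is accepted only if its
  reference matches land near the cluster's own anchors. Contig ends made
  of tandem telomere units — assessed on both the contig and the raw
  reads, since greedy assembly collapses tandem repeats — mark de novo
  telomere junctions (threshold 12 units).
* **Validation** — a call validates iff support ≥ 3 *and* support ≥ 0.2 ×
  local span depth per copy. The per-copy normalisation (span divided by
  the local copy number from read depth) keeps the rule calibrated inside
  the inverted duplication, where span depth doubles but junction-crossing
  fragments come from a single product locus. The published analysis says
  only that span depth "statistically distinguishes" real junctions from
  noise; this two-criterion rule is our documented stand-in, validated
  against simulated truth only.
* **Segmentation** — recursive binary splitting of read depth with a
  t-like statistic (threshold 12, minimum segment 200 bp), excluding a
  300 bp edge margin where coverage ramps down. Per-base depth is
  autocorrelated over the read length, which inflates the statistic, so
  segments shorter than 500 bp are absorbed into the neighbour with the
  closer mean before copy numbers are assigned (segment mean ÷ genome
  median depth, rounded).

## Classification

`foldback_inversion` requires all four signature features: a copy-0
segment overlapping the cassette; a copy-≥2 segment centromeric of it; a
validated, assembled inversion-geometry junction within 200 bp of the
duplication's telomeric boundary (taken as the span from the deletion's
end to the duplication's start, since coverage ramps blur the
transition); and the assembled junction sequence. Resolution classes:
class 3 for ≥ 2 secondary junctions; class 1 when the secondary junction
joins the two members of the declared inverted homology pair *and* the
captured fragment is at copy 1; class 2 when it targets a
homology/repeat feature and a telomere-anchored donor segment is at copy
≥ 2; telomere-addition resolution for telomeric junctions (or when no
secondary junction exists, the duplication having been healed by
telomere); microhomology resolution for short-microhomology joins (≤ 10
nt — the literature separates "microhomology-mediated" from
"homology-mediated" by name only, so the numeric ceiling is our choice).
Coarse (pair-resolution) secondary junctions match features with a
≈ one-insert pad — homology-bridged junctions rarely yield unmapped
junction reads, which is biologically faithful: such junctions are defined
by their anchor pairs, not by split reads.

## Rate statistics

The Luria–Delbrück pmf follows the standard recursion `p_0 = e^{-m}`,
`p_r = (m/r) Σ_{i<r} p_i/(r−i+1)`. Because the tail decays only like
`m/r`, tabulating to cumulative mass `1 − 10⁻⁹` is impractical for any
`m` of order one; sampling therefore uses the exact equivalent
compound-Poisson form (Poisson(m) mutations, clone sizes `⌊1/U⌋` with
`P(k) = 1/(k(k+1))`), and the likelihood censors jackpot counts above
1000 with the analytic tail mass. The Ma–Sandri–Sarkar MLE is found by
golden-section search on ln m over [10⁻⁴, 50]; the 95% CI uses the
standard log-scale approximation `σ_ln m = 1.225·m^(−0.315)/√C` — a
documented stand-in for the cited-literature CI method, validated here by
coverage simulation (≈ 93% at m ∈ {0.5, 1, 2, 5}). All-zero data return
rate 0 with the upper bound from the probability of observing C zero
cultures.

The bootstrap proportion CI resamples the n 0/1 observations 100,000
times and takes empirical 2.5/97.5% quantiles; when the foldback or
non-foldback count is zero, one observation of the missing class is added
first (n grows by one — the pseudo-count adds an observation rather than
reallocating one), so intervals cannot degenerate to points. Subtype-rate
propagation combines the relative interval half-widths of rate and
proportion in quadrature (formulas in the README); a negative lower bound
is floored at 0 and flagged.

Fisher's exact test sums hypergeometric point probabilities ≤ that of the
observed table within a 1 + 10⁻⁷ relative tolerance (the dominant
two-sided convention); it is implemented from `scipy.stats.hypergeom`
point masses and cross-checked against `scipy.stats.fisher_exact` in the
tests. Mann–Whitney U wraps scipy with exact enumeration for untied
samples of ≤ 8 and the tie-corrected normal approximation otherwise.

## Randomness and problem sizes

One master seed feeds named substreams (genome, reads, batch,
fluctuation, bootstrap) so stages can be re-run independently. The test
suite and the acceptance script use toy scales chosen for statistical
sufficiency at interactive runtimes: a 20 kb genome at 30× coverage and
0.2% error, 50 planted foldback genomes plus unrearranged controls for
recovery, 100-replicate coverage simulations of 50 cultures each, 400
random sequences against the brute-force enumeration oracle, and 100,000
bootstrap resamples.

## What passing tests do and do not show

The benchmark demonstrates internal correctness: the caller recovers
exactly what the generative model planted, at the planted coverage and
error rate, on a genome engineered to have unambiguous mapping outside
declared repeats. It does not demonstrate performance on real sequencing
data — no indel or quality-dependent errors, no long repeat families, no
mappability structure, no library-preparation artifacts, no multi-step
rearrangements (sequential double-hairpin events and
breakage–fusion–bridge cycles are out of scope). The printed-value checks
(Fisher tables, loop medians, propagation algebra) are exact properties
of the statistics and do not depend on the simulator. One printed
inconsistency is retained as-is: the large-loop distribution printed
alongside the short-loop one yields a per-event median of 17.5 nt under
any standard convention, while the accompanying text cites 26 nt; the
computation here pins the printed counts.
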