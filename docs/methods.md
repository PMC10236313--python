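# Methods

This note documents the models and procedures implemented in
`enhancerkit`, the defaults and why they were chosen, what the synthetic
study does and does not emulate, and the numerical conventions that make
runs reproducible byte for byte.

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention); 1-based dialects
are converted at parse time. Overlap requires ≥ 1 shared bp; adjacent
half-open intervals ([100,200) vs [200,300)) do not overlap but have
distance 0, and distance between disjoint features is the gap in bp.
Proximity thresholds ("within 1 kb") are applied as distance < radius,
measured from the peak interval (not its summit) to the TSS point.
Peaks without an explicit summit use the interval midpoint.

A tag belongs to an eRNA window when its 5′ position (start for +,
end−1 for −) lies inside the window; window differential tests assign
tags by midpoint. Both conventions are deterministic under the 100-bp
3′ extension (extension never moves a 5′ end) and are stated here
because reasonable alternatives (full-overlap counting) exist.

## Tag processing

Libraries are processed in the fixed order **deduplicate → extend**:
one tag is kept per (chromosome, start, strand) key, then each tag is
lengthened 100 bp past its 3′ end (a proxy for fragment size), clamped
to chromosome bounds. The order matters — extension can clamp distinct
tags onto identical coordinates — and is asserted by a test.
Deduplication triggers only when the measured duplication rate exceeds
0.3 (configurable); the RPM/FPKM normalizer is the post-dedup count.

"Extend by 100 bp" is the implemented reading of fragment-size
extension; extending *to* a fixed fragment length is a plausible
alternative and can be had by setting the extension to
(fragment − read length). Binning defaults to midpoint counting
(exactly one bin per tag, so RPM totals are conserved); per-bin overlap
counting is available by flag. RPM = count × 10⁶ / total mapped tags
per 100-bp bin. FPKM = count × 10⁹ / (length × total) + 0.01, the
additive 0.01 being the FPKM-scale equivalent of 1 read per 10⁸ mapped
reads per kb; it floors every value and keeps ratios finite.

Anchor profiles average RPM position-wise over ±5 kb windows (100-bp
bins) around anchor points, reversing windows on − strand anchors;
anchors truncated by a chromosome end contribute only their defined
bins, and the mean at each offset is taken over contributing anchors.

## Enhancer definition

Five predicates, all evaluated (never short-circuited) so a rejected
peak reports every violated criterion: caller score ≥ 60 (MACS-scale);
no overlap with the union of H3K4me3 peaks across all supplied
conditions (the stricter reading when conditions disagree); RefSeq TSS
distance ≥ 1 kb; spliced-EST TSS distance ≥ 2 kb; H3K4me1 overlap in
some condition. Peaks on chromosomes absent from the gene annotation
are rejected `unassignable` rather than silently qualified, since the
TSS criteria cannot be certified there. Location classes partition the
qualified set: intragenic (contained in a RefSeq transcription unit),
excluded_near_tes (< 5 kb from a TES, kept out of profiling to avoid
3′ RNAPII signal), extragenic (the rest). Activity classes are
mark-overlap combinations with the ambiguous both-marks case surfaced
as `conflicted` instead of being silently resolved.

## eRNA filters

eRNAs are modeled as short (< 2 kb) bidirectional transcripts at the
p300 summit, so quantification is fixed-window by construction: plus
strand [s, s+2kb), minus strand [s−2kb, s), plus the 2–4 kb flanks.
Exclusions, each recorded independently and idempotently:

- `strand_ratio`: (n₊+1)/(n₋+1) > 5 with a symmetric 1-tag pseudocount
  (the threshold is one-directional as defined; a symmetric option
  exists because a minus-dominated locus is equally suspect).
- `flanking_signal`: a 2–4 kb flank strictly exceeding its proximal
  window (tags/bp when clamping makes lengths unequal, raw counts
  otherwise) — a long/genic-transcript signature.
- `repeat_signal`: an externally supplied per-locus repeat flag (here,
  overlap with a repeat-region BED) combined with > 1 FPKM on either
  strand; repetitiveness is not inferred from alignments.
- `rrna_homology`: any of the four windows overlapping an rRNA
  blacklist BED; no sequence search is performed.

Windows are clamped at chromosome ends and FPKM uses the clamped
length. Induction is the stimulated/unstimulated total-FPKM ratio per
matched locus (each condition normalized by its own library size); the
pseudocount floors the denominator at 0.02.

## Differential enrichment stand-in

Dedicated differential peak callers are deliberately not reimplemented;
the contribution here is the *rule* (enrichment at FDR < 0.1
intersecting qualified enhancers), so the test behind it is the
simplest defensible one: per window, a one-sided exact binomial test of
the stimulated count out of the pooled count against the depth
proportion d_s/(d_s+d_c), BH adjustment across windows, enrichment
when q < 0.1. Zero-count windows are untestable (p = 1), not errors.
Windows default to qualified-enhancer intervals padded ±500 bp.
Pre-called differential peak BEDs can be substituted wholesale. The
all-null calibration and the power of this stand-in are measured, not
assumed (see the acceptance script): at Poisson(20) null counts and
equal depths, the empirical all-null FDR sits at or below the nominal
0.1 within Monte-Carlo error, and planted 5-fold windows with ≥ 50
expected control tags are detected essentially always.

Inducible genes: samples are quantile-normalized (each column's sorted
values replaced by the mean of sorted values across columns, ties
receiving the mean reference value of their tied ranks), then per gene
an unpaired equal-variance t-test (Welch by flag) on log₂-scale values
and a log₂ fold-change threshold: inducible ⇔ LFC > 1 and p < 0.05.
Background adjustment is out of scope (synthetic matrices are generated
background-free).

## EPU assignment

The published enhancer-promoter-unit construction is richer than what
is reproduced here; the implemented rule is a documented
simplification isolated behind one interface: CTCF peak summits
partition each chromosome into blocks (duplicate summits collapse;
chromosome ends close terminal blocks; no CTCF ⇒ one block per
chromosome), and an enhancer is assigned to the nearest TSS (summit to
TSS point) sharing its block, capped at 200 kb (no cap is inherent to
the method; 200 kb is a conventional cis-regulatory range), ties toward
the lower coordinate. Non-assignment records its reason
(`no_tss_in_block`, `out_of_range`). Coarsening the partition by
removing a CTCF site can only merge blocks, so it never unassigns a
previously assigned enhancer — a tested invariant. One enhancer maps to
at most one gene; one gene may collect many enhancers.

## Occupancy and promoter dynamics

Binding sites are classified promoter > enhancer > other, promoter
windows being TSS ± 1 kb (the overlap window is not fixed by the
definitions above, so it is configurable; 1 kb mirrors the enhancer
exclusion radius). Precedence is safe because a qualified enhancer can
never sit inside a promoter window by construction. Ranking for top-N
selection orders by (−score, chromosome, start) so outputs are
byte-reproducible under permutation. Input-normalized promoter signal
is (mean IP RPM + ε)/(mean input RPM + ε) over the window with
ε = 0.01 RPM; both tracks are RPM-normalized by their own library
sizes, making the ratio invariant to matched depth changes, and the
empty-window ratio is exactly 1. Set contrasts are t-tests (paired for
matched pre/post gene sets, Welch unpaired otherwise) with degenerate
zero-variance contrasts reported as p = 1.

## The synthetic study

The generator lays features out in fixed-size *cassettes* walked along
the chromosomes with seeded jitter gaps (2 × 7 Mb by default), which
guarantees the spacing margins the enhancer rules assume and makes
every expected outcome computable at generation time into a manifest.
Planted content, per default configuration:

- 400 RefSeq-like genes (8 kb bodies, H3K4me3 at TSS), 6 EST-like
  genes, 40 inducible genes (10%), 40 control genes for the H3K9me2
  contrast.
- 50 true extragenic enhancers (20 active / 15 intermediate / 15
  poised, with the matching H3K9ac/H3K9me3 and H3K27ac/H3K27me3
  peaks), 4 intragenic, 3 near-TES; 3 qualification decoys per
  rejection class, each violating exactly one criterion (score 59,
  planted H3K4me3 overlap, TSS at < 1 kb, EST TSS at 1.5 kb, missing
  H3K4me1).
- eRNA: proximal windows Poisson(60) per strand at true loci (doubled
  in the stimulated library), flanks empty; 10 decoys per exclusion
  class at margin-safe rates (unidirectional 150:5; read-through
  flank 100 vs proximal 20; repeat 300 with a planted repeat region;
  rRNA-blacklisted at true-locus rates). Margins are chosen so that at
  these rates no stochastic threshold crossing is expected; the
  libraries are padded with uniform background kept ≥ 6 kb away from
  every locus so windows stay pure and condition depths match exactly.
- CTCF sites flank designated cassettes to create assignable (gene
  20 kb away in the same block), blocked (no TSS in block), and
  out-of-range (240 kb in a 260-kb block) EPU cases, plus extra
  boundaries at ordinary gene cassettes.
- 100 factor binding sites composed 70/8/22 percent
  enhancer/promoter/other before stimulation; 5% of sites move from
  multi-site enhancers to inducible promoters afterwards (65/13/22),
  leaving the bound-enhancer set itself unchanged. 30% of qualified
  enhancers are bound, biased toward the active class.
- H3K9me2: Poisson(600) IP tags per promoter window pre-stimulation,
  halved post-stimulation at inducible promoters only; input at 600
  throughout; all four libraries padded to 270k tags so RPM
  normalizers cancel in post/pre comparisons.
- Expression: log₂ intensities, baseline N(8, 2²) per gene, planted
  +2.0 log₂ effect in stimulated samples of induced genes, N(0, 0.25²)
  noise, 3 replicates per condition.

Counts are Poisson and expression noise is Normal on the log₂ scale —
the minimal models the downstream procedures implicitly assume. Peak
files are emitted directly (peak calling is out of scope). Identical
config + seed yields byte-identical files; the default study runs the
full pipeline in well under a minute on one CPU.

One generator choice deserves a note: the baseline log₂-intensity sd is
2.0. Quantile normalization of a matrix in which 10% of genes shift up
by 2.0 log₂ units *compresses* the measured fold changes (the reference
distribution's upper tail absorbs part of the shift) — a real property
of normalizing asymmetric differential expression, visible in the
worked example (planted 2.0 measured as ≈ 1.8). The narrower the
baseline distribution, the stronger the compression; at sd 1.0 a
fraction of planted genes drops below the LFC > 1 gate, so the default
reflects the wide dynamic range of real log₂ intensity data
(roughly 6–14), where the effect is mild.

**What passing does not show.** The synthetic study validates the
*rules*, not biology: peaks are planted (no peak-calling noise, no
overlapping features beyond the designed decoys), window counts are
exactly Poisson with clean backgrounds, replicate variance is exactly
the nominal noise, and repeat/rRNA structure is reduced to interval
overlap. Real data adds mappability artifacts, copy-number and GC
effects, fragment-size misestimation, annotation errors, and
correlated replicates, none of which are emulated. Recovery rates on
the fixture are therefore upper bounds, not expectations for real
libraries.

## Problem sizes used

Tests and the acceptance script run the default study (112 p300 peaks,
90 eRNA loci, 400 genes, ~1.2 M tags across ten libraries), a
1,000-peak random qualification oracle, and a 5,000-window × 50-replicate
null calibration of the differential stand-in — sizes chosen so the
whole suite completes in a few minutes on a single CPU while keeping
every Monte-Carlo margin comfortable.

## Known limitations

- Transcription units are single intervals (no exon structure, no
  GFF/GTF parsing); EST TSS lists are inputs, not reconstructed.
- The EPU rule is the simplification described above, not the full
  published construction.
- The differential stand-in has no replicate dispersion model; with
  biological replicates a negative-binomial framework would be the
  right substitute, supplied as external differential peaks.
- eRNA windows are fixed at 2 kb; no transcript assembly or
  polyadenylation analysis is attempted.
- Condition labels are opaque strings; the pipeline imposes no design
  beyond unstimulated/stimulated pairs.
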