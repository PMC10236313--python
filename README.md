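# enhancerkit

Enhancer annotation, enhancer-RNA (eRNA) filtering, and stimulus-dependent
occupancy dynamics from ChIP-seq and stranded RNA-seq tag data.

## The problem

Type I interferon induction (e.g. by the dsRNA mimic poly I:C in mouse
embryonic fibroblasts) rewires chromatin at both enhancers and promoters:
p300/H3K4me1-marked distal elements gain acetylation and bidirectional
eRNA transcription, chromatin regulators redistribute from enhancers to
the promoters of induced genes, and repressive promoter H3K9me2 is lost
specifically at inducible genes. Quantifying these events from sequencing
data requires a chain of small, rule-based computations — enhancer
qualification from peak calls, strand-aware window counting, exclusion
filters, differential enrichment, insulator-aware enhancer-gene
assignment, input-normalized signal ratios — that are usually buried in
one-off scripts. `enhancerkit` implements that chain as a tested,
reusable library, and ships a seed-deterministic synthetic-data generator
with a ground-truth manifest so every stage can be validated end to end
without any external download.

It is aimed at regulatory-genomics analysts who already have peak calls
(MACS/CCAT-style), tagAlign-format aligned reads, and gene tables, and
who want the enhancer/eRNA/occupancy bookkeeping to be explicit,
deterministic, and testable.

## What it computes

**Enhancer qualification.** A p300 peak qualifies as an enhancer iff
score ≥ 60, no overlap with any H3K4me3 peak from any condition,
distance > 1 kb to every RefSeq TSS, distance > 2 kb to every spliced-EST
TSS, and ≥ 1 bp overlap with an H3K4me1 peak. Qualified peaks fully
contained in a RefSeq transcription unit are *intragenic*; the rest are
*extragenic* unless within 5 kb of a transcription end site (excluded to
keep 3′-end RNAPII signal out of profiles). Activity classes come from
acetylation/repressive-mark overlap: active (H3K9ac⁺), poised
(H3K9me3⁺), intermediate (neither); H3K27ac/H3K27me3 classing is
available behind the same engine.

**eRNA quantification.** Around each extragenic summit *s*, stranded tag
counts in four fixed windows — plus strand `[s, s+2kb)`, minus strand
`[s−2kb, s)`, and the 2–4 kb flanks — with exclusion filters for
unidirectional transcription ((n₊+1)/(n₋+1) > 5), read-through
(flank > proximal), flagged repetitive loci above 1 FPKM, and rRNA
blacklist overlap. FPKM carries a pseudocount floor of 0.01 (1 read per
10⁸ mapped reads per kb).

**Tag-level signal.** Reads are deduplicated (when duplication is high),
extended 100 bp past their 3′ end, binned into 100-bp windows, and
reported as reads per million mapped reads (RPM); anchor profiles
average RPM ±5 kb around feature sets, strand-aware.

**Inducible calling.** Enhancers are inducible when they intersect an
H4ac or H3K9ac window enriched in the stimulated condition over the
unstimulated library (one-sided exact binomial test with
Benjamini–Hochberg adjustment, FDR < 0.1 — a documented stand-in for a
dedicated differential peak caller; externally called differential peaks
can be supplied instead). Genes are inducible when, after quantile
normalization, log₂ fold change > 1 with unpaired Student's t-test
p < 0.05.

**Enhancer-promoter units (EPU).** CTCF summits partition chromosomes
into blocks; each extragenic enhancer is assigned to the nearest gene
TSS in its block within 200 kb, or reports why not.

**Occupancy dynamics.** Factor binding sites are classified against
promoter windows (TSS ± 1 kb) and qualified enhancers (promoter
precedence), yielding per-condition colocalization fractions, top-N
analyses, and bound-enhancer fractions per activity class. Promoter
signal (e.g. H3K9me2) is quantified as (mean IP RPM + ε)/(mean input
RPM + ε) per promoter, with paired/unpaired set contrasts.

## Worked example

The `analysis/` scripts run the whole study on synthetic data:

```bash
python analysis/01_simulate_fixture.py            # writes results/fixture/
python analysis/02_run_pipeline.py                # writes results/run/
python analysis/03_enhancer_and_erna_recovery.py
python analysis/04_inducible_sets_and_epu.py
python analysis/05_occupancy_dynamics.py
```

With the default configuration (seed 0) this prints, among other lines:

```
qualified enhancers: 97/112 (locations: {'intragenic': 4, 'extragenic': 90, 'excluded_near_tes': 3})
eRNA loci passing all filters: 50/90 (exclusions: {'repeat_signal': 10, 'rrna_homology': 10, 'flanking_signal': 10, 'strand_ratio': 10})
inducible genes: 40/400; inducible enhancers: 21
median eRNA induction: 1.95-fold
promoter overlap rises from 8% to 13% with stimulation (enhancer overlap 70% -> 65%)
bound enhancers overall: 29.9% (active 65%, intermediate 24%, poised 7%)
promoter H3K9me2 (input-normalized) post/pre stimulation:
inducible    0.502976
random       1.000933
```

Reading: of 112 planted p300 peaks, the 97 built to satisfy the
qualification rules qualify and each of the 15 decoys is rejected for
exactly the criterion it violates; all 50 true bidirectional eRNA loci
pass while each decoy class (unidirectional, read-through, repeat, rRNA)
is excluded for its planted reason; the planted 2-fold eRNA induction
and 2-fold promoter H3K9me2 loss at inducible (but not control) genes
are recovered; and the planted redistribution of factor binding sites
from enhancers toward inducible promoters (70/8/22 → 65/13/22 percent
enhancer/promoter/other) is recovered exactly.

The same pipeline runs on real inputs by pointing `PipelineConfig` (or
`enhancerkit run-all --input DIR`) at BED/narrowPeak peak files,
tagAlign libraries, refFlat-style gene tables and a chrom.sizes file.

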