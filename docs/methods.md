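# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED native). SNP tables
(1-based positions) and GTF gene models (1-based inclusive) are converted on
read and back-converted on write. "Overlap" always means at least one shared
base pair; no minimum-overlap fraction is used anywhere, because every
membership question in the pipeline (SNP in DHS, SNP in peak, peak in
interior, TSS in loop) is naturally a point-in-interval or ≥1-bp test.
Chromosome names are compared verbatim. A SNP is modeled as the 1-bp
interval `[pos0, pos0+1)`; indels and multi-base variants are out of scope.

Symmetric windows around a point (`window_around`) are closed on the point:
±`f` bp produces `[pos−f, pos+f+1)`, clipped at the chromosome start, so a
feature exactly `f` bp away still counts. This matters at the ±1 kb CTCF
summit windows, where the funnel's boundary behavior is part of the
contract (999 bp hits, 1,001 bp does not).

## High-confidence peaks

A high-confidence (HC) peak set is the replicate-intersection rule: the
replicate-1 peaks that overlap at least one replicate-2 peak. Reported
coordinates are taken from replicate 1 rather than from the clipped
intersection, because downstream CTCF windows need the original summit
offsets; a `coords="merged"` variant returns union spans instead (summits
dropped). Replicate-intersection pipelines in the wild do both; rep1 is
the default here and the merged variant is a flag away. The reproducible events themselves are
symmetric in the replicates — swapping the arguments changes the reported
coordinates but not which peak pairs qualify.

## Genomic context

Context classification against gene models mimics HOMER-style annotators
reduced to five categories: promoter (default 1 kb upstream to 100 bp
downstream of the TSS, strand-aware), exon, TTS (±1 kb of the transcript
end), intron (inside the gene span but none of the above), intergenic.
Priority is fixed in that order; ties between genes within a category break
by distance from the query midpoint to the TSS. The full HOMER vocabulary
(5′UTR, non-coding, …) is deliberately collapsed — evidence-matrix figures
in this problem domain report essentially promoter/intron/intergenic — and
"other" categories map onto intergenic.

## The SNP funnel

Stages are nested by construction: a SNP outside open chromatin carries
all-false mark and loop vectors even if it happens to sit inside a peak.
The asymmetry between marks is deliberate and mirrors how the two kinds of
evidence behave: H3K27Ac membership uses the full HC peak interval (broad
histone domains), CTCF membership uses ±1 kb of the HC peak summit
(point-source binding; regulatory variants cluster near, not inside, the
motif). The per-dataset hit vectors are preserved for the evidence matrix;
the stage counts collapse them with "hit in ≥1 roster dataset" semantics.
When no loop data are attached, the two loop-stage counts are reported as
not-computed (`None`) rather than zero.

## Loops

Loops enter pre-called and are filtered on intra-chromosomal span
(midpoint-to-midpoint, default 50 kb ≤ span < 10 Mb) and contact
significance (q < 0.05, strict). Midpoints are used for spans and for
cross-dataset matching because anchors are resolution-limited bins (10 kb
here) and midpoints are stable under small re-binning shifts; the
cross-dataset matching slack defaults to one bin. Support counts the
query's own dataset. Inter-chromosomal records are representable so the
filter can reject and count them, but they have no span and never reach the
risk-loop layer. BEDPE q-values sit in the ninth column (after name and
score) by default; the column is configurable, and a missing q-value passes
the filter with the understanding that such inputs (e.g. HiChIP loop lists)
were pre-filtered upstream.

Motif-orientation classes pick the highest-scoring motif overlapping each
anchor (anchors in canonical genomic order): `+/−` convergent, `−/+`
divergent, same-strand tandem; an anchor with no motif gives `no_motif`,
and equal top scores on opposite strands give `ambiguous` rather than an
arbitrary call.

## Deserts, targets, adoption

A desert call evaluates the loop *interior* — between the inner anchor
edges, excluding the anchor bins, since the risk CTCF site itself lives in
an anchor and would otherwise falsify every desert. `is_desert` requires
zero H3K27Ac HC peaks from any roster dataset and an interior of at least
100 kb (configurable; observed deserts in repressed loci run ~200–600 kb,
and the generator's ordinary loops are kept below the threshold so desert
ground truth stays unambiguous). Anchors that touch or overlap yield no
interior and `is_desert=False`. H3K27me3 coverage is reported as a merged
base-pair fraction with no boolean threshold, because no principled cutoff
for "covered" exists.

Target-gene prediction uses the TSS, not the gene span, so calls at loop
edges are unambiguous: genes with a TSS inside any risk-loop outer span are
`within_loop`, genes within the ±1 Mb window are `within_window`, with loop
membership taking precedence. Adoption candidates are H3K27Ac sites outside
the (pre-deletion) desert interior within 2 Mb of the deleted site, merged
across roster datasets, ranked by distance to the deletion, and flagged
when they contain an H3K27Ac-stage risk SNP.

## Deletion fold changes

This layer is deliberately descriptive, matching what locus-level deletion
figures show: per-gene fold change `(mean_del + c) / (mean_ctrl + c)` with
pseudocount `c = 0.5` on library-size-normalized values, ranked by
|log2 fold change| within ±1 Mb of the deleted site, ties broken by
distance. Normalization scales every sample to a fixed counts-per-million
total: a fixed target (rather than, say, the mean library size) keeps fold
changes *exactly* invariant to rescaling any single sample's column, which
a data-dependent target would violate through the pseudocount. The top
responder is only called when it clears a 2-fold change in either
direction. Genome-wide differential-expression modeling (edgeR-style GLMs,
batch correction) is out of scope; a permutation p-value (group-label
shuffling) is available as an optional significance annotation. With n = 3
vs 3 the best achievable two-sided permutation p is 2/20, so it is a sanity
annotation, not an inference engine.

## The synthetic landscape

The generator is block-based: every planted SNP owns a disjoint genomic
slot sized for its evidence (4 kb for point evidence; anchor + interior +
anchor for loop strata), background peaks live on 25-kb centers in
dedicated zones, and the two "repressed locus" models occupy reserved
regions. Nothing can contaminate a neighboring label, which is what makes
exact-count recovery a meaningful test rather than a statistical one.

Defaults model the experiment at full scale: funnel strata 2,181 / 443 / 222 / 93 /
203 / 85 (nested; the two mark strata are disjoint by construction), nine
ChIP datasets per mark (seven cell lines, two also ± androgen) in duplicate,
five chromatin-interaction datasets, replicate reproducibility 0.8 with
replicate-2 edge jitter N(0, 50 bp) and summit jitter N(0, 20 bp)
(irreproducible peaks are isolated by ≥10 kb so the HC rule cannot rescue
them), 10-kb anchors with per-dataset jitter ±2 kb (inside the one-bin
matching slack), ordinary loop spans 54–90 kb (so a jitter-shrunk copy still
clears the 50-kb filter), q-values drawn below 0.049,
and decoy loops straddling every filter boundary (span 49,999 / 50,000 /
10,000,000; q 0.05 / 0.2; one inter-chromosomal record) in a SNP-free zone.
Motif orientation classes are drawn 50/30/20
convergent/tandem/divergent, with occasional weaker opposite-strand decoy
motifs to exercise best-motif selection.

The two repressed loci mirror the geometry of interest: a risk CTCF site
(CTCF-bound in all nine datasets, DHS-positive, summit at the SNP) in the
shared anchor of two convergent loops (220/320 kb on one chromosome,
300/715 kb cluster locus on the other) present in all five interaction
datasets; interiors free of H3K27Ac and ~83% covered by H3K27me3; a caged
gene 30 kb inside; a pre-existing enhancer 70 kb upstream of the caged TSS,
just outside the desert, carrying its own H3K27Ac-stage risk SNP; and
neighbor genes spread across the ±1 Mb window. The cluster locus adds three
secondary caged genes with smaller planted effects (10/5/3-fold), one of
them between the two partner anchors (inside only the larger loop).

Two chromosomes are used, auto-sized (~22 Mb each at full scale): 2,181
SNP blocks plus ~290 loops of ≥50 kb span cannot fit in a fixed 20 Mb, and
the stratum counts are the conditions being tested, so chromosome length is
the parameter that yields.

Expression matrices are negative-binomial (dispersion 0.1 — a typical
cell-line RNA-seq value; the clonal/pool design gives no variance model of
its own) over the locus window genes plus 2,000 unlinked "transcriptome"
rows with baselines uniform in 50–500. The transcriptome rows keep library
totals stable so a 100-fold induction of one gene cannot skew sum-based
normalization — with only window genes in the matrix, the induced gene
would inflate its own library by several-fold and the estimator would be
biased low by the same factor. Per-sample library sizes vary ±30% to
exercise normalization. Scenario effects on the caged gene default to
100 / 2 / 7 / 1 for risk-anchor, single-partner, double-partner, and
control deletions. The caged baseline is 100 counts, high enough that the
dispersion term dominates the estimator noise.

### What the generator does and does not emulate

It emulates the *logical* structure of the real inputs — nested evidence,
replicate reproducibility, cross-dataset loop support, filter boundary
cases, desert geometry, planted expression effects — with clean separation
between planted features. It does not emulate read-level noise, peak-width
or signal distributions, linkage disequilibrium among SNPs, overlapping
regulatory elements, cell-type-specific loop differences, or indirect
(trans) expression changes. Passing tests therefore certify the pipeline's
logic and arithmetic, not its robustness to messy real peak calls; on real
data, ambiguity enters through the upstream peak/loop callers, which are
outside this package.

## Numerical and testing choices

At the generator's expression conditions (dispersion 0.1, n = 3 vs 3) the
fold-change estimator for a 100-fold effect has a per-run coefficient of
variation of ≈0.26 — single runs land anywhere in roughly [50, 150]. The
estimator checks therefore assert the median over 50 seeded simulations
(which has a standard error of ~4%), the top-responder identity per run
(rank 1 in ≥95% of runs; in practice 100%), and the scenario *ordering*
per run (risk > double-partner > single-partner), with single-partner and
control medians asserted near 1–2-fold rather than per-run, since a true
2-fold and a true 1-fold effect are not separable in every 3-replicate run.

Exact oracles back the interval machinery: the overlap filter is compared
against an all-pairs scan (and against `bedtools intersect -u` as an
independent implementation), and repressive coverage against a per-base
boolean array, on 100+ seeded random instances each, with exact equality
required. All randomness flows through `numpy.random.default_rng` seeds;
regenerating a landscape with the same seed is byte-identical, which the
test suite asserts file by file.

## Known limitations

- Loop anchors are treated as given bin intervals; whether a real analysis
  would extend anchor membership beyond the bin is dataset-dependent.
- The desert call is binary on peak count; a single weak spurious peak in a
  real dataset flips it. On real data one would inspect `n_k27ac_interior`
  and peak scores rather than the flag alone.
- `evidence_matrix` reports one mark at a time; a SNP positive for both
  marks appears in both matrices.
- The permutation p-value's resolution is limited by the group sizes
  (see above); it cannot reach conventional significance at n = 3.
- The fold-change layer makes no multiple-testing adjustment and is not a
  substitute for genome-wide differential-expression analysis.
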