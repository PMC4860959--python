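# Methods notes

## Coordinate and tag conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
is converted on read. A "tag start" is always the read's 5′ end in
reference coordinates: the BED start for a Watson read, `end − 1` for a
Crick read. Whether duplicate tags should be collapsed before analysis is
assay-dependent (MNase libraries legitimately pile up at well-positioned
nucleosomes), so deduplication is an explicit flag on `read_tags`,
default off.

## Fragment-length estimation

The strand cross-correlation S(k) = Σ W(x)·C(x+k) is computed on raw
per-base tag-start counts — not binarized and not Pearson-standardized per
lag. Raw counts keep the statistic an exact pairwise-distance histogram,
which the test suite exploits: the fast implementation must equal an
O(|W|·|C|) brute-force scan bit for bit (integer-valued float64 arithmetic
is exact well below 2^53). The estimate is d = argmax S + 1, because the
two 5′ ends of one fragment of length L are L − 1 apart; ties break to the
smaller lag for determinism. The default search window is
[read length + 1, 300] bp: tag-start correlation has a phantom peak at
exactly the read length, and nucleosomal inserts in this assay class sit
near 110–160 bp, far below 300.

## Dyad mapping and normalization

Watson dyad = start + ⌊d/2⌋; Crick dyad = start − ⌊d/2⌋. The direction of
the Crick shift is forced by geometry: only a midpoint-converging shift
turns 5′ ends into center estimates. Floor (rather than round or
half-integer) shifts keep positions integral; for even d this biases the
Watson estimate by +0.5 bp and the Crick by −0.5 bp, which cancels in
strand-balanced libraries and is far below the profile feature scale.
Dyads shifted off a contig are dropped and tallied, so the conservation
law "track sum = retained tags" is checkable. Normalization divides by the
genome-average density total_mapped/mappable_span; mappable_span defaults
to the sum of contig lengths (no mappability correction — masked-region
input is accepted but not computed from alignability).

Browser coverage tracks instead extend each read to length d in its strand
direction, pile up per-base overlaps and optionally scale by 1e6/total
tags; extensions are clipped at contig ends, not dropped, matching how
such tracks are conventionally built.

## Metagene profiles

Offsets are in transcript orientation (negated for minus-strand anchors).
Per-offset denominators count only anchors whose window covers that
offset; zero-filling out-of-bounds offsets would drag profile edges toward
zero on small contigs. Exon-boundary anchors come only from
intron-containing genes. "Internal" exons exclude the first exon in
transcript order; the last exon is kept by default because its 5′ site is
a genuine intron/exon junction (an `exclude_last` flag provides the
symmetric definition). Anchors within a configurable distance of any
annotated TSS (default 250 bp for internal-exon analyses) are removed so
promoter nucleosome structure does not masquerade as boundary enrichment.
The active/silent split uses expression greater than the median of nonzero
values; any fixed threshold is arbitrary without spike-in calibration, and
the median is scale-free and configurable.

## GC enrichment

The GC window is 147 bp — the DNA content of one nucleosome — centered on
the dyad; GC is (G+C)/(window − N). Percentile bin edges are dyad-weighted
quantiles of the *total*-nucleosome GC distribution (20 bins by default),
so the x-axis is "GC percentile of bulk nucleosomes" and the curve is a
ratio of within-track fractions, invariant to sequencing depth of either
library. Bins with no total dyads are reported missing rather than zero.
The smoothing is degree-1 lowess with span 0.3 — a visual aid, never used
in any statistic.

## Association

The promoter window is −50..+500 bp around the TSS in transcript
orientation, inclusive at both ends; gene-end occupancy uses the same
window around the termination end. Expression is log2(x+1)-transformed
before Pearson correlation by default (expression magnitudes are
log-distributed; the raw option is kept for sensitivity checks). The peak
comparison rule — a mark peak qualifies when ≥10% of *its own length*
overlaps the union of reference peaks — is deliberately asymmetric, and
the track-level alternative is Pearson correlation of 500-bp-binned
counts; both are provided because published heatmaps of this kind rarely
state which construction they used.

## Splicing-event filtering

MISO mode keeps events with inclusion ≥ 1 AND exclusion ≥ 1 AND
inclusion+exclusion ≥ 10 AND |ΔΨ| ≥ 0.20 AND Bayes factor ≥ 10 (all
inclusive). The ΔΨ criterion is on magnitude: inclusion and exclusion
shifts are equally interesting. MATS mode keeps events with p ≤ 0.05,
|splicing difference| ≥ 0.0001, and a gene-expression fold-change guard
implemented as max(FC, 1/FC) ≤ threshold with threshold 10000 by default —
i.e. effectively permissive; the guard exists to discard events
explainable by expression change alone and can be tightened. Peak–event
intersection uses ≥1 bp of overlap (configurable), a weaker rule than the
10% peak-comparison criterion because event spans and peaks have very
different length scales. Filtering is idempotent and monotone in every
threshold; both properties are tested.

## Synthetic data: what it emulates

The generator builds multi-contig genomes with GC-elevated exons
(background 0.40, exonic +0.12), equal-length exons/introns laid out on
both strands, and three nucleosome populations: a phased array starting
100 bp downstream of each TSS at 175-bp spacing whose first two positions
(+1/+2) carry a lognormal per-gene promoter strength (shared by the factor
and total tracks — promoter occupancy is a chromatin property, factor
preference is layered on top); a nucleosome positioned exactly at each
internal exon 5′ site, modeling the exon-demarcating nucleosome the
boundary analysis targets; and a jittered background grid every 200 bp.
Factor sampling multiplies placement weights by
(1 + boundary_enrichment·1[within 50 bp of an internal exon 5′ site]) ·
(GC/0.5)^β, defaults 5 and 2. Fragments are round(N(d₀, σ)) with
d₀ = 156/150 bp (factor/total) and σ = 10; each fragment emits one 50-bp
single-end tag on a fair-coin strand. Expression is coupled to the
realized factor dyad count in the promoter window so that
corr(occupancy, log2-expression) equals the target ρ = 0.4 in expectation
on exactly the scale the pipeline measures. Event tables draw each
retention criterion's pass state independently at rate 0.7 and realize
values accordingly; the recorded truth label is recomputed from the
realized values by direct comparison, so impossible combinations (e.g. a
read-sum pass with both read counts zero) resolve honestly.

Default problem sizes — 2000 genes on 4×1.2 Mb contigs with 100k tags per
track, or 200 genes on 2×300 kb with 50k tags for replicate studies — keep
a full study under two seconds while leaving every per-gene statistic
well-powered.

What the generator does **not** emulate: sequence-dependent nucleosome
positioning and MNase digestion bias, spliced or multi-mapped reads,
transcript isoform diversity (one transcript per gene, uniform exon
sizes), overdispersed count noise, and any dependence between event-table
rows. Passing tests therefore demonstrate correctness of the computations
and recoverability of planted structure, not robustness to the full noise
structure of real libraries.

## Determinism

All generator randomness flows through `numpy.random.default_rng([seed,
stage])` with integer stage indices, so a fixed seed reproduces every
output file byte for byte across platforms; the pipeline itself is
deterministic, and reports are written with sorted keys and 6-digit
rounding for diffability.

## Known limitations

No paired-end support (the cross-correlation estimator exists precisely
because the data are single-end); no nucleosome peak calling; no
mappability modeling; the loess curve is descriptive only; and the
event-table filters implement fixed thresholds, not a re-derivation of the
upstream tools' posterior inference.
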