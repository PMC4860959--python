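# nucdyad

Nucleosome-resolution occupancy profiling for factor-bound chromatin, with
alternative-splicing event intersection.

`nucdyad` analyses stranded single-end tag libraries from
nucleosome-resolution ChIP-seq (MNase-digested chromatin immunoprecipitated
with a factor antibody) alongside a matched total-nucleosome (MNase-seq)
library. It answers the questions such experiments are run for: where do
factor-bound nucleosomes sit relative to transcription start sites, gene
ends and exon–intron boundaries; are they on GC-richer DNA than bulk
nucleosomes; does promoter-proximal occupancy track gene expression; and do
the factor's binding sites coincide with differentially spliced events
called by isoform-inference tools.

## Method

**Fragment length from strand cross-correlation.** Single-end reads flank
each DNA fragment from opposite ends, so with per-base tag-start counts
W(x) and C(x) on the Watson and Crick strands, the cross-correlation

&nbsp;&nbsp;&nbsp;&nbsp;S(k) = Σ_x W(x)·C(x + k)

peaks at k = d − 1, where d is the average insert length. The search
window starts above the read length to avoid the phantom peak there.

**Dyad mapping.** Each Watson tag start is shifted by ⌊d/2⌋ forward and
each Crick 5′ end by ⌊d/2⌋ backward, so the per-base tag frequency at
position i approximates the probability that i is a nucleosome center
(dyad). Tracks are normalized by the genome-average density
(total mapped dyads / mappable bp), so 1.0 means "average occupancy".

**Metagene profiles.** Anchor sets (TSS, transcription termination end,
exon 5′/3′ sites — optionally restricted to first or internal exons of
intron-containing genes, split by expression, and excluding anchors within
±250 bp of any TSS) give mean normalized dyad density at offsets −flank..
+flank in transcript orientation, with total-nucleosome background
subtraction.

**GC enrichment.** Every dyad contributes the GC fraction of the 147 bp
window centered on it; positions are binned by percentile of the
total-nucleosome GC distribution, and the curve reports
(factor fraction)/(total fraction) per bin with a loess fit.

**Association.** Per-gene dyad counts in a strand-oriented −50..+500 bp
promoter window are Pearson-correlated with log2(expression + 1); peak sets
are compared with a ≥10%-of-peak-length overlap rule and signal tracks with
binned Pearson correlation.

**Splicing intersection.** MISO-style event tables are filtered on
inclusion reads ≥ 1, exclusion reads ≥ 1, inclusion + exclusion ≥ 10,
|ΔΨ| ≥ 0.20 and Bayes factor ≥ 10; MATS-style tables on p-value, splicing
difference ≥ 0.0001 and an expression fold-change guard. Retained events
are intersected with peak intervals (≥1 bp) and gene sets are summarized as
2–4-way Venn partitions.

A fully deterministic synthetic-data generator (`nucdyad.synthetic_data`)
produces genomes, annotations, tag libraries, expression and event tables
with known ground truth, so the whole pipeline is testable offline.

## Worked example

```sh
nucdyad simulate --out-dir demo --seed 1
nucdyad estimate-d --tags demo/factor_tags.bed
nucdyad estimate-d --tags demo/total_tags.bed
nucdyad correlate --tags demo/factor_tags.bed --d 156 \
    --annotation demo/annotation.gtf --expression demo/expression.tsv
nucdyad filter-ase --events demo/miso_events.tsv --mode miso \
    --out demo/miso_filtered.tsv
```

prints

```
d=156 peak_lag=155
d=150 peak_lag=149
r=0.4177 p=2.73e-85 n=2000
retained 51/300
```

The simulator drew factor fragments at d₀ = 156 bp and total fragments at
d₀ = 150 bp; both estimates are exact here. The correlation of promoter
dyad occupancy with log-expression recovers the generator's coupling
target of 0.4, and the event filter retains 51 of 300 synthetic events —
exactly the rows whose values satisfy all five retention criteria.
`nucdyad all --factor-tags … --out-dir out` runs every stage and writes
`out/report.json` plus all intermediate tracks, profiles and tables.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and numerical
choices.
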