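# inductr

Most bacteria in the human gut carry integrated phage genomes (prophages),
but only a fraction of computationally predicted prophages can actually be
induced into lytic replication — the rest are cryptic, domesticated, or
mis-predicted. `inductr` implements the computational pipeline of an
experimental induction screen: it decides, from sequencing-coverage and
k-mer evidence, which predicted prophages really induce, dereplicates and
profiles the resulting phage genomes, and compares induced against
non-induced prophages to look for the genetic footprints of prophage
domestication.

It is a library plus a thin `inductr` CLI, aimed at microbiome
bioinformaticians who already have prophage predictions and per-sample read
mappings and need the downstream induction logic with testable,
deterministic behaviour.

## What it computes

**Coverage-based induction calling.** An induced prophage multiplies its
copy number, so its reads pile up above the host chromosome. Per 100-bp bin
x_p of a predicted region, against host bins x_h with median x̃ and median
absolute deviation MAD:

    z_ave = mean( 0.6745 · (x_p − x̃) / MAD )
    d     = ( mean(x_h) − mean(x_p) ) / sqrt( (s_h² + s_p²) / 2 )
    fold  = mean(x_p) / median(x_h)

A region is retained as induced when `z_ave ≥ 3.5`, or when `fold ≥ 2` and
`|d| > 0.7`. Called regions are boundary-refined by trimming flanking bins
below 25% of the region's mean coverage; overlapping predictions are merged
(half-open intervals, ≥ 1 bp overlap). Putative phage contigs are validated
by hallmark genes (terminase large subunit ≥ 265 aa, portal ≥ 245 aa, major
head ≥ 186 aa — cut-offs derivable as half the mean of the middle 80% of
reference lengths).

**Dereplication.** ANI is the alignment-length-weighted identity over BLAST
blocks (overlaps resolved longest-first); AF is the merged aligned span over
the shorter genome. Greedy length-descending clustering at 99%/85%
dereplicates induced phages; 95%/85% defines species and selects
induced/non-induced comparison pairs restricted to hosts sequenced in a
condition where the partner induced.

**Community-scale calling.** Within defined synthetic communities, a
prophage species is induced when a member genome is covered ≥ 85% of its
length at ≥ 2× the host's length-normalized depth in ≥ 3 of 5 replicates;
the k-mer route requires a 2× excess of unique-k-mer duplicity over the host
(detection thresholds: phage — 0.25 k-mer coverage, 10 reads, 100 unique
k-mers; host — 10 reads, 18,000 unique k-mers; k = 21, canonical).

**Virome profiling.** Fractional abundance
`(reads/length) / (total_reads/50,000)`, renormalized to sum to 1 per
virome; presence requires ≥ 70% breadth.

**Comparative genomics.** Per-category gene enrichment (two-sided Fisher,
Hochberg-adjusted) with percent frequency change
`100·(f_cry − f_in)/f_in`, and gap-event calling between high-similarity
prophage pairs: an unaligned inter-block stretch ≥ 50 bp on both genomes is
an HGT (replacement) event, on one genome only an insertion–deletion event;
terminal gaps are excluded.

Every input can be generated by `inductr.synthetic` with known ground truth
(lysogen genomes, negative-binomial coverage tracks, community reports,
alignment fixtures), so the whole pipeline runs and is tested without any
external data.

## Worked example

Simulate a 70-kb lysogen with a 10-kb prophage at 20 kb, draw a coverage
track with eightfold induction, and call induction:

```sh
inductr simulate lysogen --host-length 60000 --insert 20000:10000:ph1 --seed 3 --out-dir .
inductr simulate coverage --genome-length 70000 --truth-bed truth.bed \
    --induction-fold 8 --seed 3 --out-dir .
inductr call-induction --depth depth.tsv --regions truth.bed \
    --refined-bed refined.bed --out calls.tsv
```

`calls.tsv` then contains:

```
sample  region  contig   z_ave               cohens_d             fold               induced
        ph1     lysogen  21.67553928571429   -3.882760311027012   8.756896551724138  True
```

The region's bins sit ~21.7 robust standard deviations above the host
median, with a large (negative, i.e. elevated) effect size and an ~8.8-fold
coverage excess — comfortably past the `z_ave ≥ 3.5` rule — and
`refined.bed` recovers the planted boundaries exactly
(`lysogen 20000 30000 ph1`).

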