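# Methods

## Coverage model and the induction decision

The caller works on mean per-base depth in fixed 100-bp bins of a host
contig. Bins overlapping any predicted prophage region by at least 1 bp are
phage bins of that region; host bins are all bins inside *no* prediction,
so that a second induced prophage on the same genome cannot contaminate the
null background. The last bin of a contig may be partial; it carries the
per-base mean over its actual span and participates like any other bin.

Three statistics are computed per region and sample:

* **Average modified z-score** — `mean(0.6745·(x_p − x̃)/MAD)` with x̃ the
  median and MAD the median absolute deviation of the host bins. 0.6745 is
  the MAD-to-σ consistency constant, so values are on the scale of ordinary
  z-scores under a Gaussian null. When MAD = 0 (flat host coverage) the
  statistic is undefined and returned as NaN rather than infinity; the
  decision then rests on the other clause.
* **Cohen's d** — pooled-SD standardized mean difference
  `(mean(x_h) − mean(x_p))/√((s_h²+s_p²)/2)` with sample SDs (ddof = 1).
  It is negative for induced regions; the decision rule uses |d|. NaN when
  both sides are constant.
* **Fold change** — mean phage depth over the *median* host depth. The
  median baseline is robust to other elevated regions; a mean baseline is
  available via `baseline="mean"`. NaN when the baseline is zero.

Decision: induced ⇔ `z_ave ≥ 3.5` **or** (`fold ≥ 2` **and** `|d| > 0.7`).
The d comparison is strict, the z and fold comparisons inclusive. NaN
components fail only their own clause, so the two clauses degrade
independently on degenerate tracks.

**Boundary refinement** trims flanking bins with depth below 25% of the
region's mean bin depth. The threshold is computed once from the initial
region and not recomputed during trimming: this is the simplest reading of
the rule, it makes refinement idempotent, and it makes the "everything
trimmed" outcome impossible (all bins below 0.25× their own mean would
force the sum below a quarter of itself), which the implementation still
guards defensively. Only flanking bins are removed — interior dips, e.g.
deleted cargo inside an induced prophage, survive. Merging of overlapping
predictions requires a ≥ 1 bp overlap; half-open abutting intervals stay
separate, and a merged region keeps the maximum completeness of its
members.

**Hallmark validation.** A contig counts as a genuine phage if it has at
least one hallmark-gene hit at or above its length cut-off. Cut-offs are
derived from a reference protein set as half the mean of the middle 80% of
lengths (values outside the 10th–90th percentile dropped, linear
interpolation percentiles); the shipped defaults are terminase large
subunit 265 aa, portal 245 aa, major head 186 aa.

## Dereplication and pair selection

ANI between two genomes is the alignment-length-weighted mean identity of
their blocks after resolving query-side overlaps longest-first with
trimming; AF is the merged aligned span divided by the shorter genome's
length. Clustering is greedy representative-linkage: genomes are visited in
length-descending order (ties broken lexicographically by id, making the
result fully deterministic) and join the first cluster whose
*representative* they match at or above both thresholds. Representative
linkage rather than single linkage prevents chaining through intermediate
genomes. Thresholds: 99/85 for dereplicating induced phage contigs, 95/85
for species and for induced/non-induced comparison pairs. Comparison pairs
are further restricted to non-induced prophages whose host was sequenced in
at least one condition in which the induced partner induced — otherwise the
partner's silence carries no information.

## Community callers

Host-level quantities aggregate over the host's contigs weighted by length:
mean depth `Σ(depth_c·len_c)/Σ len_c`, and likewise duplicity; host reads
and unique k-mers are summed. Read-mapping rule: a phage passes a replicate
iff breadth ≥ 0.85 and depth ≥ 2× the host mean (host absent → the
replicate fails); k-mer rule: a replicate counts iff the phage is detected
and its duplicity is ≥ 2× the host's, or — when the host itself is
undetected — iff the phage is detected at all. A genome is induced at a
quorum of 3 of 5 replicates (both configurable), and a species is induced
when at least one member genome reaches quorum by itself; passes are not
pooled across members, the strictest reading of the replicate rule.

Unique k-mers use k = 21 and canonical form (lexicographic minimum of the
k-mer and its reverse complement), matching what k-mer classifiers do
implicitly; windows containing N are skipped. A k-mer is unique to a genome
iff it occurs in no other database genome, so duplicated genomes shadow
each other to zero — the pipeline's reason for masking prophage regions out
of host genomes before database construction.

## Virome profiling

Fractional abundance `(reads/length)/(total_reads/50,000)` retains the
50,000-read scale constant as a per-virome convention (configurable; it
cancels under the subsequent normalization to sum 1). Genomes with zero
reads contribute zero and are effectively excluded from the normalization
denominator; a virome with no mapped genome yields NaN. Presence requires
breadth ≥ 0.70, inclusive.

## Comparative genomics

Gene-category frequencies come in two modes: *total* (category genes over
all annotated genes of the set) and *presence* (genomes containing the
category over genomes in the set). Enrichment between the induced and a
comparison set tests the per-category 2×2 table (category vs rest × set)
with a two-sided Fisher exact test, Hochberg-adjusted across categories;
zero-margin tables get p = 1 and a `degenerate` flag. The attached percent
frequency change is `100·(f_cry − f_in)/f_in`, NaN when `f_in = 0`.

Gap events between a high-similarity pair are read off adjacent collinear
alignment blocks: with ≥ 50 bp unaligned on *both* genomes the inter-block
stretch is a replacement signature and is called HGT; with ≥ 50 bp on
exactly one genome it is an insertion–deletion event. This interpretation
is the only one that makes the two definitions mutually exclusive.
Stretches before the first or after the last block touch a sequence end and
are never called. Rearranged (non-collinear) or overlapping block sets are
rejected rather than guessed at.

## Summaries

The induction ledger has one row per tested (isolate, region, condition).
Induced fractions: isolates induced in ≥ 1 condition over all isolates;
high-quality (completeness > 50%) regions induced in ≥ 1 condition over all
high-quality regions; species clusters likewise. Percentages round half-up
to integers. A lysogen, for polylysogeny purposes, is an isolate with ≥ 1
*induced* prophage; a polylysogen has ≥ 2. Rank correlations, ANOVA and
similar tests on real measurements are left to standard tools — the package
emits the tidy tables they consume.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) lysogen genomes with i.i.d. composition at a
chosen GC and prophages inserted at fixed host offsets, with exact truth
coordinates; (ii) per-bin depth tracks, negative binomial with mean
`base_depth` (× `induction_fold` inside prophages) and dispersion r —
Poisson in the r → ∞ limit; (iii) community report tables where induced
phages draw breadth/depth/duplicity well above every threshold and
non-induced well below, hosts always detected; (iv) alignment fixtures
where planted HGTs replace a segment and planted indels delete one, so the
emitted blocks encode the events exactly.

Defaults: base depth 30×, dispersion r = 10 (per-bin CV ≈ 37% — a
deliberately noisy guess, since real binned-depth dispersion varies widely
with library and genome), bin 100 bp, GC 0.45, 5 replicates. What is *not*
simulated: reads and read errors, repeats and mapping artefacts,
contamination, GC-coverage bias, partially induced mixtures. Passing tests
therefore demonstrate the correctness and calibration of the decision
logic, not robustness to real-data mapping pathologies.

## Evaluation operating points

Null calibration runs 200 independent 60-kb tracks with a 10-kb candidate
region at fold 1; the measured false-positive rate of the full retention
rule is ~0–1%. Boundary recovery runs 200 tracks at tenfold induction,
depth 30×, with the candidate padded by 5 bins per side to emulate an
imprecise upstream prediction; recovery means both refined boundaries
within one bin of truth. The tenfold point represents a strongly induced
prophage; the 25%-of-mean trim rule has a theoretical floor at fold 4
(where the threshold equals host mean), and near it refinement necessarily
degrades regardless of implementation. Community caller evaluation uses 20
genomes with 8 induced under wide generator margins, where a correct caller
must reach sensitivity = specificity = 1. The end-to-end pass simulates 40
lysogens with 1–3 prophages each, induces ~35% of regions at eightfold, and
checks the called fraction against the planted one. These sizes keep the
whole suite and the acceptance script in the tens of seconds on one CPU.

## Known limitations

* The fold-change numerator/denominator convention (mean over median) is a
  documented choice; the exact formula behind "coverage fold increase" is
  not fixed by the rule itself, so both baselines are exposed.
* Gap-event calling refuses rearranged block sets instead of attempting
  synteny-aware chaining.
* The greedy clustering is order-deterministic but, like all greedy
  dereplication, not invariant to perturbing genome lengths near ties.
* One published worked-example percentage (68/274 quoted as 24%) is
  inconsistent with any single rounding convention (half-up gives 25); it
  is excluded from the reproduced tallies.
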