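# Methods

## Scope and data model

`lncfocal` operates on four inputs: a gene annotation (GTF with
`gene_type`/`transcript_type` attributes), per-sample segmented log2
copy-number profiles (SEG-style TSV: sample, chrom, start, end,
seg_mean), a genes × samples read-count matrix, and per-sample subtype
labels.  All internal coordinates are 0-based half-open; GTF (1-based,
closed) is converted on read and write.  Read alignment and counting,
copy-number segmentation and peak significance estimation (GISTIC-style)
are upstream of the package: counts, segments and peak intervals are
consumed, not produced.

## lncRNA catalog

A gene qualifies as a lncRNA when every transcript carries one of the
non-coding biotypes (`antisense`, `lincRNA`, `non_coding`,
`processed_transcript`), every mature transcript length (summed exon
length) is at least 200 nt, and the gene symbol is absent from a
user-supplied coding-symbol blacklist.  The blacklist is an input file
(empty by default) standing in for whatever coding-gene symbol catalog
the analyst trusts; matching is exact but case-insensitive — a
documented judgment call, since symbol collisions in annotations are
not case-normalized consistently.  Pseudogenes pass through unflagged:
they are neither coding nor lncRNA, and keeping them as a third class
leaves the coding/lncRNA contrasts clean.

Intergenic lncRNAs additionally require a gap strictly greater than
5 kb between the gene span (outermost transcript boundaries) and the
nearest coding gene span on both sides; overlap counts as distance 0
and a side with no coding gene counts as infinitely distant.  All
threshold comparisons in the package (5 kb, 200 nt, RPKM cutoffs, t and
amplitude thresholds) are strict inequalities, and the boundary cases
are pinned by tests.

## Gene-level copy number

Each gene's amplitude in a tumor is the `seg_mean` of the segment
containing its span; when the span crosses segment boundaries, the
minimum over the overlapping segments.  The rationale is asymmetric
biology: amplification must cover the whole gene to increase its
dosage, while a partial deletion already disrupts it — the minimum
encodes both.  A gene overlapping no segment is undetermined (NaN,
never silently 0), and genes undetermined in more than `max_missing`
(default 0.5) of samples are excluded from the matrix and reported
separately.  The implementation is cross-checked against a
per-basepair brute-force oracle on random toy genomes.

Amplified/deleted calls use ±0.3 log2 as defaults.  **These thresholds
are a package choice**: roughly a single-copy change in an impure
tumor; nothing in the analysis depends on them other than the
"recurrently altered" stratum below, and they are configurable.

## Expression

RPKM[g, s] = counts[g, s] · 10⁹ / (length[g] · library[s]), with gene
length the union of exonic bases across transcripts (matching
union-based counting) and library size the total annotation-mapped
count of the sample, so the conservation identity
Σ_g RPKM·length·library/10⁹ = Σ_g counts holds per sample to numerical
precision.  Log-scale values add a pseudo value of 0.01 before log2.
PolyA-enrichment ratios compare counts-per-million between a polyA+
and a total-RNA library with a pseudo count per library.

Tile coverage divides a region into 1000 nt tiles spaced 500 nt apart;
a read interval counts once in every tile it overlaps (tiles are
analyzed independently).  Per-sample normalization divides by the
median of the top ceil(5% · n_tiles) tiles ranked by raw count (ties
broken by genomic position), computed over the whole genome; samples
with a zero divisor are excluded with a warning.  Read pairs are
collapsed to one interval.

## Dosage correlation

Pearson correlation between gene-level CNA and log2 RPKM across tumors
(Spearman available by option), computed per gene over samples with a
determined copy-number value; undefined when fewer than 10 pairs
remain or either variable is constant (flagged, never zero-filled).
The stratified comparison (max RPKM > 3 and altered in > 15 tumors,
both strict) isolates the regime where dosage response is measurable:
genes below the expression floor contribute only noise, and genes
without recurrent alteration have no dosage signal to detect.

## Subtype signatures and classification

Tumors are split into a discovery set of exactly `n_per_set` (default
200) and a validation set holding all remaining samples (an odd sample
lands in validation).  Genes with more than 50% zero-count values are
excluded.  The per-gene, per-subtype statistic is a two-sample t
(subtype vs all remaining tumors) on log-scale expression — Welch's
unequal-variance form by default, pooled variance by option.
Signature genes have |t| > 4 in exactly one subtype; genes passing in
two or more subtypes are ambiguous and dropped.  Classification scores
each tumor and subtype as the difference between the mean z-score of
the subtype's induced genes and that of its repressed genes (a missing
direction contributes 0); ties resolve to the first subtype in the
configured order and are flagged.  Z-scores use the population
standard deviation and are computed within each sample set
independently — discovery parameters are not carried into validation —
because each set is meant to stand on its own; a switch allows reusing
discovery parameters.

## Focal-amplification calling

A candidate region is a center gene plus its two coding-neighbor gene
bodies as flanks (buildable automatically from the annotation).  Per
tumor: center = gene-level CNA of the center gene; u, d = minimum raw
segment amplitude over each flank interval (honoring "minimum over the
region"; falls back to the flank gene's gene-level amplitude when
segments are unavailable).  Calls: focal iff c−u > 0.2 and c−d > 0.2;
marked focal iff both > 0.4; broad iff not focal and c > 0.4; else
none.  The focal/marked criteria are differences and therefore
invariant to per-sample amplitude shifts; the broad criterion is not —
this asymmetry is intentional and tested.  Samples with an
undetermined center or flank are excluded from every denominator.

Downstream statistics:

* **Induction** — fold change of linear-scale mean RPKM, focal
  (focal ∪ marked focal) vs remaining tumors; when the rest mean is 0 a
  pseudo value of 0.01 is added to both means.  A median-based fold is
  available by option.  Significance by two-sided Wilcoxon rank-sum.
* **Neighbor induction** — the same contrast applied to each flank
  gene; a lncRNA-directed amplification should leave both flat.
* **Group enrichment** — 2×2 table of subgroup flag × amplified with
  frequency ratio (a/(a+b))/(c/(c+d)) and two-sided Fisher exact p.

### Exact small-sample tests

The rank-sum test enumerates the exact permutation distribution of the
rank sum when both groups have ≤ 12 members, via a shift-algorithm
dynamic program over doubled midranks, so ties are handled exactly;
the two-sided p doubles the smaller tail (capped at 1).  Larger groups
use the normal approximation with tie and continuity correction; the
two paths agree within 0.02 absolute at the crossover sizes.  Fisher's
two-sided p uses the point-probability convention — the sum of
hypergeometric point probabilities ≤ that of the observed table (with
a 1e-9 relative tolerance for floating-point equality) — the most
common convention, stated here because conventions differ.  Both tests
are verified against independent oracles: full enumeration and exact
rational arithmetic in the test suite, and scipy's implementations as
a second, independent route.

## Synthetic cohorts

The generator produces the structure the analyses assume, with every
planted fact recorded in a truth table.

**Genome and annotation.**  Two chromosomes (45 + 35 Mb) carrying 1,500
coding and 500 lncRNA genes with 1–2 transcripts of 2–3 exons,
interleaved with length-scaled random gaps.  One lncRNA (the focal
target) is planted mid-chromosome-1 with coding neighbors 55 kb and
65 kb away — an intergenic island of ~128 kb mirroring the geometry of
a reported amplified intergenic lncRNA locus — and at least one
antisense lncRNA is nested inside a coding host.

**Copy number.**  Per sample, chromosomes are tiled with 3–10 Mb
segments with amplitude N(0, 0.05).  40% of tumors gain the arm
carrying the focal target (+0.5 log2, a typical arm-gain frequency and
amplitude for a chromosome-1q-like arm in serous tumors); 4% carry a
narrow amplicon (width uniform 50–120 kb, amplitude +0.6–1.5 log2)
covering the full target gene and confined to the intergenic space,
optionally extending partially into a neighbor with probability 0.1.

**Counts.**  Expected count = library · weight / Σweight with
weight(g, s) = (length/1000) · 2^(b_g + k·CNA + effects + ε), where the
baseline b_g ~ N(−2, 4) with lncRNAs offset by −6.5 log2 (yielding the
characteristic pattern that far fewer lncRNAs than coding genes ever
exceed 1 RPKM), dosage slope k = 1, planted subtype effects of
±2 log2 on 15 lncRNAs per subtype (drawn from the better-expressed
half of lncRNAs so the effects are observable above the count floor),
and an extra +4 log2 activation of the focal target in focally
amplified tumors — copy-number gain alone (≤ 1.5 log2) cannot produce
the tens-fold induction observed at such loci, so the generator models
the implied transcriptional co-activation explicitly, with the
magnitude as a package choice.  ε ~ N(0, 1.25²) is per-gene per-tumor
biological variability: inter-tumor heterogeneity dominates counting
noise in real cohorts, and without it planted subtype effects would be
implausibly easy to detect (and, conversely, would make every planted
gene "ambiguous" under the one-vs-rest rule, since a clean effect in
one subtype surfaces as a strong negative in the others).  Counts are
gamma-Poisson (negative binomial) with dispersion 0.2; dispersion 0
together with zero noise terms gives the deterministic limiting case
used to verify the dosage model exactly.  Library sizes are uniform
20–80 million.

All randomness flows from a single seed through named sub-streams
(annotation, labels, segments, counts), so a fixed seed reproduces
every output byte and one component's draw count cannot perturb
another's.

**What the generator does not emulate:** GC and mappability biases,
isoform switching, purity/ploidy variation, co-amplification of
passenger neighbors, batch effects, and correlated gene–gene expression
modules.  Passing recovery tests therefore demonstrates correctness of
the implementations under the stated model, not robustness to every
artifact of real tumor data.

## Problem sizes and numerical choices

The validation suite runs the full pipeline on 400-tumor, 2,000-gene
cohorts — large enough for the 200/200 discovery/validation design and
for ~16 expected focal tumors at 4% frequency, while keeping the whole
suite fast.  Oracle cross-checks use exhaustive enumeration where it is
cheap (all 2×2 tables with N ≤ 20; rank-sum enumeration at small group
sizes, with scipy's exact distribution covering tie-free cases up to
12 per group).  Tolerances: conservation and z-score identities to
1e-9; oracle agreement to 1e-12 where arithmetic is exact.

## Known limitations

* The ±0.3 alteration thresholds and the Pearson default are package
  choices where the analysis tradition is silent; both are exposed as
  parameters.
* "Undetermined" copy number means only "no overlapping segment";
  probe-sparse segments are not modeled.
* The deletion analog of the focal caller is the sign-flipped rule via
  configuration; no deletion-specific caller is provided.
* Sex chromosomes are treated like autosomes (no ploidy correction).
* Survival analysis, gene-set enrichment, coding-potential assessment
  and raw-read processing are out of scope.
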