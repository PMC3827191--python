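# lncfocal

Integrative analysis of long non-coding RNAs (lncRNAs) in tumor cohorts:
from a gene annotation and segmented copy-number profiles to gene-level
dosage, RPKM expression, subtype-selective lncRNA signatures, and calls
of focal DNA amplification targeting intergenic lncRNA loci.

Most cancer driver genes reveal themselves through recurrent *focal*
copy-number alteration — narrow amplifications or deletions centered on
the selected gene.  lncRNAs should be targetable by the same mechanism,
but because they are weakly expressed and interleaved with coding genes,
detecting a lncRNA-directed amplification requires combining a carefully
filtered lncRNA catalog, gene-level copy number, expression dosage
response and a caller that separates narrow gains from arm-level ones.
`lncfocal` implements that whole chain for cohort-scale data (a few
hundred tumors), plus a synthetic-cohort generator with planted ground
truth so every step can be validated end to end.

## Core definitions and rules

* **lncRNA catalog** — a gene is a lncRNA iff all its transcripts have
  biotype `antisense`, `lincRNA`, `non_coding` or `processed_transcript`,
  every mature (spliced) transcript is ≥ 200 nt, and its symbol does not
  collide with a coding gene symbol.  The *intergenic* subset requires
  > 5 kb (strict) from the nearest coding gene span on both sides.
* **Gene-level copy number** — for each gene and tumor, the log2 segment
  amplitude of the covering segment; when the gene span crosses segment
  boundaries, the **minimum** amplitude over the overlapping segments
  (full coverage is needed to amplify a gene; partial loss already
  disrupts it).  Genes undetermined in > 50% of tumors are dropped.
* **Expression** — RPKM = counts · 10⁹ / (gene length · library size),
  with log2(RPKM + 0.01) as the log layer.  Dosage response is the
  per-gene correlation r(CNA, log2 RPKM) across tumors, reported overall
  and for the stratum max RPKM > 3 and altered in > 15 tumors.
* **Subtype signatures** — one-vs-rest t statistic per gene and subtype
  on a 200-tumor discovery half; signature genes have |t| > 4 in exactly
  one subtype.  Classification score per tumor and subtype:
  mean z(induced genes) − mean z(repressed genes); predict the argmax,
  validate on the withheld half.
* **Focal amplification** — with center amplitude c and flank minima
  u, d over the two neighboring coding-gene bodies: *focal* iff
  c − u > 0.2 and c − d > 0.2; *marked focal* iff both > 0.4; *broad*
  iff not focal and c > 0.4.  Downstream: linear-scale mean fold change
  of the target in focal vs remaining tumors with a Wilcoxon rank-sum
  p-value (exact for small groups), and Fisher's exact test for
  enrichment of amplification in a sample subgroup.

## Worked example

```python
import lncfocal as lf

cfg = lf.SimConfig(seed=1)          # 400 tumors, ~2,000 genes
cohort = lf.simulate(cfg)           # annotation + labels + segments + counts
ann = cohort.annotation

cn = lf.assign_gene_cna(cohort.segments, ann)
spec = lf.region_spec_from_annotation(ann, cfg.focal_target_gene)
calls = lf.call_focal_amplification(cn, spec, segments=cohort.segments)
print(calls.counts().to_dict())
de = lf.differential_expression_focal(cohort.counts.rpkm, calls,
                                      cfg.focal_target_gene)
print(f"fold change: {de['fold_change']:.1f}, p = {de['p_value']:.2e}")
```

prints

```
{'none': 234, 'broad': 150, 'marked_focal': 16}
fold change: 44.3, p = 2.44e-13
```

The 16 tumors called `marked_focal` are exactly the 16 in which the
generator planted a narrow (50–120 kb) amplicon over the intergenic
target lncRNA; the 150 `broad` tumors carry the arm-level gain, which
lifts center and flanks together and therefore never satisfies the
focal contrast.  The target's RNA is ~44-fold higher in focal tumors
(rank-sum p ≈ 2e-13), while its two coding neighbors stay flat
(folds 1.06 and 0.99, p > 0.1 — `lf.neighbor_induction`), the signature
of an amplification directed at the lncRNA itself.

A command-line interface mirrors the library
(`lncfocal simulate | annotate | cn-map | express | correlate | subtype
| focal`); run `lncfocal --help`.

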