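"""Focal-amplification screening and calling, with downstream statistics.

A focal amplification is a narrow copy-number gain whose center locus
exceeds both flanking regions, as opposed to a broad (arm-level) gain
that lifts center and flanks together.  Given a candidate intergenic
locus and its two coding-neighbor gene bodies as flanks, each tumor is
classified by comparing the center gene's copy-number amplitude (CNA,
log2) with the minimum segment amplitude over each flank:

* ``focal``        — center minus both flank minima > 0.2
* ``marked_focal`` — both differences > 0.4 (implies focal)
* ``broad``        — not focal, but center CNA > 0.4
* ``none``         — otherwise

Downstream statistics: linear-scale mean fold change of the target's
expression in focal vs remaining tumors with a Wilcoxon rank-sum
p-value; the same contrast for the flanking genes (which a genuinely
lncRNA-targeted amplification should leave untouched); and a Fisher
exact test for enrichment of amplification in a flagged sample group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneAnnotation, nearest_coding_neighbors
from .cn import GeneCNMatrix, SegmentSet
from .stats import fisher_exact_2x2, rank_sum_test

log = logging.getLogger(__name__)

DEFAULT_FOCAL_DELTA = 0.2    # log2 center-minus-flank margin
DEFAULT_MARKED_DELTA = 0.4
DEFAULT_BROAD_THRESHOLD = 0.4
DEFAULT_MAX_CODING = 5
FOCAL_CLASSES = frozenset({"focal", "marked_focal"})
FOLD_PSEUDO = 0.01  # RPKM units, applied to both means when the rest mean is 0


class FocalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Peak screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRegion:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise FocalError(f"peak {self.label!r}: empty interval")


def read_peaks_bed(path) -> list[PeakRegion]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            label = fields[3] if len(fields) > 3 else ""
            peaks.append(PeakRegion(fields[0], int(fields[1]), int(fields[2]), label))
    return peaks


def screen_peaks(
    peaks: list[PeakRegion],
    annotation: GeneAnnotation,
    max_coding: int = DEFAULT_MAX_CODING,
) -> pd.DataFrame:
    """Per-peak gene content report.

    A gene overlaps a peak when its span intersects the peak interval.
    ``narrow`` flags peaks with at most ``max_coding`` overlapping coding
    genes; ``lncrna_only`` flags peaks with no coding gene and at least
    one lncRNA — the configuration in which the lncRNA itself is the most
    plausible amplification target.
    """
    rows = []
    for peak in peaks:
        coding, lnc = [], []
        for g in annotation.genes:
            s, e = g.span
            if g.chrom != peak.chrom or s >= peak.end or e <= peak.start:
                continue
            if annotation.is_coding(g.gene_id):
                coding.append(g.gene_id)
            elif annotation.is_lncrna.get(g.gene_id, False):
                lnc.append(g.gene_id)
        rows.append(
            {
                "label": peak.label,
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "n_coding": len(coding),
                "n_lncrna": len(lnc),
                "coding_genes": ",".join(sorted(coding)),
                "lncrna_genes": ",".join(sorted(lnc)),
                "narrow": len(coding) <= max_coding,
                "lncrna_only": len(coding) == 0 and len(lnc) >= 1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Focal calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """A candidate locus and its flanking coding-gene regions.

    Flanks are the neighbor gene bodies (0-based half-open intervals on
    the same chromosome); they must not overlap the center gene span.
    """

    center_gene: str
    chrom: str
    upstream_flank: tuple[int, int]
    downstream_flank: tuple[int, int]
    upstream_gene: str | None = None
    downstream_gene: str | None = None

    def __post_init__(self):
        for name, (s, e) in (
            ("upstream_flank", self.upstream_flank),
            ("downstream_flank", self.downstream_flank),
        ):
            if s >= e:
                raise FocalError(f"{name} is empty")


def region_spec_from_annotation(annotation: GeneAnnotation, center_gene: str) -> RegionSpec:
    """Build a RegionSpec from the center gene's nearest coding neighbors."""
    gene = annotation.gene(center_gene)
    rep = nearest_coding_neighbors(gene, annotation)
    if rep.left is None or rep.right is None:
        raise FocalError(f"{center_gene}: missing a coding neighbor")
    return RegionSpec(
        center_gene=center_gene,
        chrom=gene.chrom,
        upstream_flank=rep.left.span,
        downstream_flank=rep.right.span,
        upstream_gene=rep.left.gene_id,
        downstream_gene=rep.right.gene_id,
    )


def read_region_spec(path) -> RegionSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RegionSpec(
        center_gene=raw["center_gene"],
        chrom=raw["chrom"],
        upstream_flank=tuple(raw["upstream_flank"]),
        downstream_flank=tuple(raw["downstream_flank"]),
        upstream_gene=raw.get("upstream_gene"),
        downstream_gene=raw.get("downstream_gene"),
    )


@dataclass
class FocalCallSet:
    """Per-sample categorical amplification call for one candidate region.

    ``table`` columns: sample, call (none/broad/focal/marked_focal),
    center, up_min, down_min.  ``skipped`` lists samples with an
    undetermined center amplitude (excluded from all denominators).
    """

    table: pd.DataFrame
    skipped: list[str]

    def samples_in(self, classes) -> list[str]:
        return list(self.table.loc[self.table["call"].isin(classes), "sample"])

    def frequency(self, classes=FOCAL_CLASSES) -> float:
        """Fraction of called samples in the given classes."""
        if not len(self.table):
            return float("nan")
        return float(self.table["call"].isin(classes).mean())

    def counts(self) -> pd.Series:
        return self.table["call"].value_counts()


def call_focal_amplification(
    cn: GeneCNMatrix,
    spec: RegionSpec,
    segments: SegmentSet | None = None,
    focal_delta: float = DEFAULT_FOCAL_DELTA,
    marked_delta: float = DEFAULT_MARKED_DELTA,
    broad_threshold: float = DEFAULT_BROAD_THRESHOLD,
) -> FocalCallSet:
    """Classify each sample's amplification of the candidate region.

    The center amplitude is the gene-level CNA of ``spec.center_gene``;
    flank minima are the minimum segment amplitude over each flank
    interval (from raw segments when available, falling back to the
    gene-level amplitude of the named flank gene otherwise).  Samples
    with an undetermined center amplitude are skipped and logged.
    """
    if spec.center_gene not in cn.matrix.index:
        raise FocalError(f"center gene {spec.center_gene!r} not in copy-number matrix")
    center_row = cn.matrix.loc[spec.center_gene]

    def flank_min(sample: str, interval: tuple[int, int], gene_id: str | None) -> float:
        if segments is not None:
            return segments.min_amplitude(sample, spec.chrom, *interval)
        if gene_id is not None and gene_id in cn.matrix.index:
            return float(cn.matrix.at[gene_id, sample])
        return float("nan")

    rows, skipped = [], []
    for sample in cn.samples:
        center = float(center_row[sample])
        if not math.isfinite(center):
            skipped.append(sample)
            continue
        up_min = flank_min(sample, spec.upstream_flank, spec.upstream_gene)
        down_min = flank_min(sample, spec.downstream_flank, spec.downstream_gene)
        if not (math.isfinite(up_min) and math.isfinite(down_min)):
            skipped.append(sample)
            continue
        d_up, d_down = center - up_min, center - down_min
        if d_up > marked_delta and d_down > marked_delta:
            call = "marked_focal"
        elif d_up > focal_delta and d_down > focal_delta:
            call = "focal"
        elif center > broad_threshold:
            call = "broad"
        else:
            call = "none"
        rows.append(
            {"sample": sample, "call": call, "center": center,
             "up_min": up_min, "down_min": down_min}
        )
    if skipped:
        log.warning("%d samples skipped (undetermined center or flank)", len(skipped))
    return FocalCallSet(table=pd.DataFrame(rows), skipped=skipped)


# ---------------------------------------------------------------------------
# Downstream statistics
# ---------------------------------------------------------------------------

def differential_expression_focal(
    rpkm: pd.DataFrame,
    calls: FocalCallSet,
    target: str,
    focal_classes=FOCAL_CLASSES,
    fold_statistic: str = "mean",
) -> dict:
    """Target expression in focally amplified vs remaining tumors.

    Fold change is the ratio of linear-scale RPKM group means (medians
    with ``fold_statistic="median"``); when the rest-group mean is 0 a
    pseudo value of 0.01 is added to both means.  The p-value is a
    two-sided Wilcoxon rank-sum test (exact for small groups).
    """
    if target not in rpkm.index:
        raise FocalError(f"target {target!r} not in expression matrix")
    focal_samples = [s for s in calls.samples_in(focal_classes) if s in rpkm.columns]
    called = [s for s in calls.table["sample"] if s in rpkm.columns]
    rest = [s for s in called if s not in set(focal_samples)]
    if not focal_samples:
        raise FocalError("empty focal group")
    if not rest:
        raise FocalError("empty comparison group")
    x = rpkm.loc[target, focal_samples].to_numpy(dtype=float)
    y = rpkm.loc[target, rest].to_numpy(dtype=float)
    agg = np.mean if fold_statistic == "mean" else np.median
    mf, mr = float(agg(x)), float(agg(y))
    fold = (mf + FOLD_PSEUDO) / (mr + FOLD_PSEUDO) if mr == 0 else mf / mr
    _, p = rank_sum_test(x, y)
    return {
        "gene": target,
        "fold_change": fold,
        "p_value": p,
        "mean_focal": mf,
        "mean_rest": mr,
        "n_focal": len(x),
        "n_rest": len(y),
    }


def neighbor_induction(
    rpkm: pd.DataFrame,
    calls: FocalCallSet,
    spec: RegionSpec,
    focal_classes=FOCAL_CLASSES,
) -> dict[str, dict]:
    """The focal-vs-rest expression contrast applied to each flank gene."""
    out = {}
    for side, gene_id in (("upstream", spec.upstream_gene), ("downstream", spec.downstream_gene)):
        if gene_id is None:
            raise FocalError(f"{side} flank gene not named in region spec")
        out[side] = differential_expression_focal(rpkm, calls, gene_id, focal_classes)
    return out


def subtype_enrichment(calls: FocalCallSet, group_flag: pd.Series) -> dict:
    """Enrichment of amplification (focal or marked focal) in a flagged group.

    ``group_flag`` maps sample -> bool; every called sample must have a
    flag.  Returns the 2x2 table (rows flag true/false, columns amplified
    vs not), the frequency ratio (a/(a+b)) / (c/(c+d)), and the two-sided
    Fisher exact p-value.  Degenerate margins give ratio NaN and p = 1.
    """
    table = calls.table
    missing = [s for s in table["sample"] if s not in group_flag.index]
    if missing:
        raise FocalError(f"{len(missing)} called samples lack a group flag")
    flags = group_flag.loc[table["sample"]].to_numpy(dtype=bool)
    amplified = table["call"].isin(FOCAL_CLASSES).to_numpy()
    a = int((flags & amplified).sum())
    b = int((flags & ~amplified).sum())
    c = int((~flags & amplified).sum())
    d = int((~flags & ~amplified).sum())
    if (a + b) == 0 or (c + d) == 0:
        ratio = float("nan")
        p = 1.0
    else:
        f1 = a / (a + b)
        f2 = c / (c + d)
        ratio = f1 / f2 if f2 > 0 else float("inf") if f1 > 0 else float("nan")
        p = fisher_exact_2x2(a, b, c, d)
    return {"table": [[a, b], [c, d]], "frequency_ratio": ratio, "p_value": p}
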