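"""Gene-level copy number from segmented profiles.

Segmented copy-number data (one log2 amplitude per genomic segment per
sample, as produced by circular binary segmentation) is mapped onto gene
coordinates: a gene fully contained in one segment takes that segment's
amplitude; a gene crossing segment boundaries takes the *minimum*
amplitude over the segments it overlaps (amplification must cover the
whole gene to raise its dosage, while partial deletion already disrupts
it); a gene overlapping no segment is undetermined.  Genes undetermined
in more than half the samples are dropped from the matrix.

SEG files are TSV with columns ``sample, chrom, start, end, seg_mean``;
coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation

log = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]

DEFAULT_MAX_MISSING = 0.5
DEFAULT_AMP_THRESHOLD = 0.3   # log2; a single-copy gain in an impure tumor
DEFAULT_DEL_THRESHOLD = -0.3


class SegmentError(ValueError):
    """Malformed or inconsistent segment input."""


@dataclass
class SegmentSet:
    """Per-sample segmented log2 copy-number intervals.

    Wraps a DataFrame with columns ``sample, chrom, start, end, seg_mean``.
    Within a sample, segments on one chromosome must not overlap.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.table = validate_segments(self.table)

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.table[self.table["sample"] == sample]

    def min_amplitude(self, sample: str, chrom: str, start: int, end: int) -> float:
        """Minimum seg_mean over segments overlapping [start, end); NaN if none."""
        sub = self.table[
            (self.table["sample"] == sample)
            & (self.table["chrom"] == chrom)
            & (self.table["start"] < end)
            & (self.table["end"] > start)
        ]
        return float(sub["seg_mean"].min()) if len(sub) else float("nan")


def validate_segments(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEG_COLUMNS if c not in table.columns]
    if missing:
        raise SegmentError(f"missing SEG columns: {missing}")
    table = table[SEG_COLUMNS].copy()
    table["start"] = table["start"].astype(np.int64)
    table["end"] = table["end"].astype(np.int64)
    table["seg_mean"] = table["seg_mean"].astype(float)
    bad = table.index[table["start"] >= table["end"]]
    if len(bad):
        raise SegmentError(f"row {bad[0]}: start >= end")
    if not np.isfinite(table["seg_mean"]).all():
        bad = table.index[~np.isfinite(table["seg_mean"])]
        raise SegmentError(f"row {bad[0]}: non-finite seg_mean")
    for (sample, chrom), grp in table.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
        if overlap.any():
            row = g.index[1:][overlap][0]
            raise SegmentError(
                f"row {row}: overlapping segments for sample {sample} on {chrom}"
            )
    return table.reset_index(drop=True)


def read_segments(path) -> SegmentSet:
    """Read and validate a SEG-style TSV."""
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SegmentError(f"cannot parse SEG file {path}: {exc}") from exc
    return SegmentSet(table)


def write_segments(segments: SegmentSet, path) -> None:
    segments.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneCNMatrix:
    """Genes x samples log2 copy-number amplitudes with explicit missingness.

    ``matrix`` holds NaN for undetermined entries (never silently 0).
    ``missingness`` is the per-gene fraction of undetermined samples among
    retained genes; ``dropped`` lists genes excluded for missingness above
    the threshold, with their missingness fraction.
    """

    matrix: pd.DataFrame
    missingness: pd.Series
    dropped: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def amplitude(self, gene_id: str, sample: str) -> float:
        return float(self.matrix.at[gene_id, sample])


def assign_gene_cna(
    segments: SegmentSet,
    annotation: GeneAnnotation,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> GeneCNMatrix:
    """Map segment amplitudes onto gene spans.

    Per gene and sample the assigned amplitude is the minimum ``seg_mean``
    over all segments overlapping the gene span (equal to the covering
    segment's amplitude when the gene is fully contained in one segment);
    NaN when no segment overlaps.  Genes with missingness > ``max_missing``
    are dropped from the matrix and reported in ``dropped``.
    """
    samples = segments.samples
    genes = annotation.genes
    values = np.full((len(genes), len(samples)), np.nan)

    # per (sample, chrom): sorted arrays for interval queries
    indexed: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (sample, chrom), grp in segments.table.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        indexed[(sample, chrom)] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["seg_mean"].to_numpy(),
        )

    for j, sample in enumerate(samples):
        for i, gene in enumerate(genes):
            key = (sample, gene.chrom)
            if key not in indexed:
                continue
            starts, ends, amps = indexed[key]
            gs, ge = gene.span
            # overlapping segments: start < ge and end > gs; segments are
            # sorted and non-overlapping, so they form a contiguous run
            lo = int(np.searchsorted(ends, gs, side="right"))
            hi = int(np.searchsorted(starts, ge, side="left"))
            if hi > lo:
                values[i, j] = amps[lo:hi].min()

    matrix = pd.DataFrame(values, index=[g.gene_id for g in genes], columns=samples)
    missingness = matrix.isna().mean(axis=1)
    keep = missingness <= max_missing
    dropped = missingness[~keep]
    if len(dropped):
        log.info("dropped %d genes with missingness > %.2f", len(dropped), max_missing)
    return GeneCNMatrix(
        matrix=matrix.loc[keep], missingness=missingness[keep], dropped=dropped
    )


def call_altered(
    cn: GeneCNMatrix,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series]:
    """Ternary amplified/neutral/deleted calls and per-gene altered counts.

    Amplified iff amplitude > ``amp_threshold`` (strict); deleted iff
    amplitude < ``del_threshold`` (strict); undetermined entries are
    neutral and excluded from the altered count.  Returns ``(calls,
    altered_counts)`` where calls hold {1, 0, -1}.
    """
    if amp_threshold <= del_threshold:
        raise ValueError("amp_threshold must exceed del_threshold")
    m = cn.matrix
    calls = pd.DataFrame(0, index=m.index, columns=m.columns, dtype=np.int8)
    calls = calls.mask(m > amp_threshold, 1).mask(m < del_threshold, -1)
    calls = calls.where(m.notna(), 0).astype(np.int8)
    altered_counts = (calls != 0).sum(axis=1)
    return calls, altered_counts


def write_gene_cn(cn: GeneCNMatrix, path) -> None:
    """Write the gene x sample matrix as TSV with NA for undetermined."""
    cn.matrix.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")
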