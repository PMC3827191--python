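"""Expression quantification: RPKM, log2 layers, polyA ratios, tile coverage.

This module consumes gene-level read counts (counting in exons is assumed
done upstream in intersection-strict mode) and derives RPKM — reads per
kilobase of transcript per million mapped reads:

    rpkm[g, s] = counts[g, s] * 1e9 / (gene_length[g] * library_size[s])

where gene length is the union of exonic bases and library size is the
total of annotation-mapped reads for the sample.  Log-scale values add a
pseudo value of 0.01 before the log2 to avoid log of zero.

Tile-coverage profiles divide a region into partially overlapping 1000 nt
tiles spaced 500 nt apart; raw per-tile read counts are normalized by the
median of the top 5% expressed tiles of each sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_LOG_PSEUDO = 0.01      # RPKM units
DEFAULT_RPKM_PREVALENCE_THRESHOLD = 1.0
DEFAULT_TILE = 1000            # nt
DEFAULT_STEP = 500             # nt
DEFAULT_TOP_FRACTION = 0.05


class ExpressionError(ValueError):
    pass


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """RPKM layer from counts, gene lengths (nt) and library sizes (reads)."""
    gene_lengths = gene_lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if gene_lengths.isna().any() or (gene_lengths <= 0).any():
        raise ExpressionError("every gene needs a positive length")
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ExpressionError("every sample needs a positive library size")
    return (
        counts.astype(float)
        .mul(1e9)
        .div(gene_lengths, axis=0)
        .div(library_sizes, axis=1)
    )


def log_transform(rpkm: pd.DataFrame, pseudo: float = DEFAULT_LOG_PSEUDO) -> pd.DataFrame:
    """log2(rpkm + pseudo); the pseudo value keeps zeros finite."""
    if pseudo <= 0:
        raise ExpressionError("pseudo must be positive")
    return np.log2(rpkm + pseudo)


@dataclass
class ExpressionMatrix:
    """Counts plus derived RPKM and log2-RPKM layers.

    Library sizes are the column sums of counts over all annotated genes,
    so the RPKM conservation identity

        sum_g rpkm[g, s] * length[g] * library[s] / 1e9 == sum_g counts[g, s]

    holds exactly per sample.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    log_pseudo: float = DEFAULT_LOG_PSEUDO
    library_sizes: pd.Series = field(init=False)
    rpkm: pd.DataFrame = field(init=False)
    log2_rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.counts < 0).any().any():
            raise ExpressionError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.rpkm = compute_rpkm(self.counts, self.gene_lengths, self.library_sizes)
        self.log2_rpkm = log_transform(self.rpkm, self.log_pseudo)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def max_rpkm(self) -> pd.Series:
        """Per-gene maximum RPKM across samples."""
        return self.rpkm.max(axis=1)

    def zero_fraction(self) -> pd.Series:
        """Per-gene fraction of zero-count (undetermined) samples."""
        return (self.counts == 0).mean(axis=1)


def expression_prevalence(
    rpkm: pd.DataFrame,
    gene_classes: pd.Series,
    threshold: float = DEFAULT_RPKM_PREVALENCE_THRESHOLD,
) -> dict[str, float]:
    """Per gene class, the fraction of genes with max RPKM strictly above
    ``threshold`` in at least one sample.  Empty classes are omitted."""
    gene_classes = gene_classes.reindex(rpkm.index)
    expressed = rpkm.max(axis=1) > threshold
    out = {}
    for cls, members in expressed.groupby(gene_classes):
        if len(members):
            out[cls] = float(members.mean())
    return out


def polya_ratio(
    counts_polya: pd.Series,
    counts_total: pd.Series,
    library_polya: float,
    library_total: float,
    pseudo: float = 1.0,
) -> pd.Series:
    """Per-gene log2 polyA+ vs total-RNA enrichment.

    Each library is scaled to counts per million; a pseudo count (also in
    cpm scale for its own library) stabilizes lowly covered genes:

        log2( (cpm_polyA + pseudo_cpm_polyA) / (cpm_total + pseudo_cpm_total) )
    """
    if not counts_polya.index.equals(counts_total.index):
        raise ExpressionError("polyA and total counts must cover the same genes")
    if library_polya <= 0 or library_total <= 0:
        raise ExpressionError("library sizes must be positive")
    cpm_a = (counts_polya + pseudo) * 1e6 / library_polya
    cpm_t = (counts_total + pseudo) * 1e6 / library_total
    return np.log2(cpm_a / cpm_t)


# ---------------------------------------------------------------------------
# Tile coverage
# ---------------------------------------------------------------------------

@dataclass
class TileCoverageProfile:
    """Sliding-tile read-density profile over a region.

    ``tiles`` is a DataFrame (chrom, start, end); ``raw`` and ``normalized``
    are tiles x samples.  Normalization divides each sample's counts by the
    median of its top-5% tiles (ranked by raw count, ties broken by
    position), computed over all that sample's tiles genome-wide.
    """

    region: tuple[str, int, int]
    tiles: pd.DataFrame
    raw: pd.DataFrame
    normalized: pd.DataFrame
    divisors: pd.Series
    excluded_samples: list[str]

    def group_mean(self, samples: list[str]) -> pd.Series:
        """Average normalized track over a named sample subset."""
        present = [s for s in samples if s in self.normalized.columns]
        if not present:
            raise ExpressionError("no requested samples in profile")
        return self.normalized[present].mean(axis=1)


def _tile_starts(start: int, end: int, tile: int, step: int) -> np.ndarray:
    if end - start < tile:
        raise ExpressionError("region shorter than one tile")
    return np.arange(start, end - tile + 1, step, dtype=np.int64)


def _count_tiles(
    intervals: np.ndarray, starts: np.ndarray, tile: int
) -> np.ndarray:
    """Number of intervals overlapping each tile [s, s+tile).

    ``intervals`` is an (n, 2) array; a read spanning two tiles counts once
    in each (tiles are analyzed independently).
    """
    counts = np.zeros(len(starts), dtype=np.int64)
    if len(intervals) == 0:
        return counts
    iv = intervals[np.argsort(intervals[:, 0])]
    iv_starts, iv_ends = iv[:, 0], iv[:, 1]
    order_by_end = np.sort(iv_ends)
    for k, s in enumerate(starts):
        # overlap: iv_start < s+tile and iv_end > s
        n_start_before = np.searchsorted(iv_starts, s + tile, side="left")
        n_end_before = np.searchsorted(order_by_end, s, side="right")
        counts[k] = n_start_before - n_end_before
    return counts


def tile_coverage(
    alignments: dict[str, pd.DataFrame],
    region: tuple[str, int, int],
    tile: int = DEFAULT_TILE,
    step: int = DEFAULT_STEP,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    chrom_sizes: dict[str, int] | None = None,
) -> TileCoverageProfile:
    """Normalized tile-coverage profile over ``region``.

    ``alignments`` maps sample -> DataFrame(chrom, start, end) of aligned
    read (pair) intervals.  The per-sample normalization divisor is the
    median raw count of the top ``ceil(top_fraction * n_tiles)`` tiles,
    computed over the whole genome (``chrom_sizes`` if given, otherwise the
    extent of each sample's alignments).  Samples whose divisor is zero are
    excluded with a warning.
    """
    chrom, rstart, rend = region
    starts = _tile_starts(rstart, rend, tile, step)
    tiles = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + tile})

    raw = {}
    divisors = {}
    excluded = []
    for sample, aln in alignments.items():
        aln_chrom = aln[aln["chrom"] == chrom]
        raw[sample] = _count_tiles(
            aln_chrom[["start", "end"]].to_numpy(dtype=np.int64), starts, tile
        )
        # genome-wide divisor over all chromosomes present
        all_counts = []
        chroms = (
            chrom_sizes.keys() if chrom_sizes is not None else aln["chrom"].unique()
        )
        for c in chroms:
            sub = aln[aln["chrom"] == c]
            if chrom_sizes is not None:
                extent = chrom_sizes[c]
            else:
                extent = int(sub["end"].max()) if len(sub) else 0
            if extent < tile:
                continue
            c_starts = _tile_starts(0, extent, tile, step)
            all_counts.append(
                _count_tiles(sub[["start", "end"]].to_numpy(dtype=np.int64), c_starts, tile)
            )
        counts_all = np.concatenate(all_counts) if all_counts else np.zeros(0)
        divisors[sample] = _top_tile_median(counts_all, top_fraction)
        if divisors[sample] == 0:
            excluded.append(sample)
            log.warning("sample %s has zero coverage divisor; excluded", sample)

    raw_df = pd.DataFrame(raw, index=tiles.index)
    keep = [s for s in raw_df.columns if s not in excluded]
    normalized = raw_df[keep] / pd.Series(divisors)[keep]
    return TileCoverageProfile(
        region=region,
        tiles=tiles,
        raw=raw_df,
        normalized=normalized,
        divisors=pd.Series(divisors, dtype=float),
        excluded_samples=excluded,
    )


def _top_tile_median(counts: np.ndarray, top_fraction: float) -> float:
    """Median of the top ceil(fraction * n) tiles by raw count.

    Ranking is by count descending with ties broken by position (stable
    sort on the negated counts).
    """
    n = len(counts)
    if n == 0:
        return 0.0
    k = max(1, math.ceil(top_fraction * n))
    order = np.argsort(-counts, kind="stable")
    top = counts[order[:k]]
    return float(np.median(top))


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED3+ file of alignment intervals into (chrom, start, end)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 3:
        raise ExpressionError("BED needs at least 3 columns")
    out = table.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out
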