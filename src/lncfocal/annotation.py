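"""Gene-model parsing and lncRNA classification.

A long non-coding RNA (lncRNA) gene is defined here as a gene whose
transcripts all carry one of the non-coding biotypes ``antisense``,
``lincRNA``, ``non_coding`` or ``processed_transcript``, whose mature
(spliced) transcripts are all at least 200 nt long, and whose symbol does
not collide with a known protein-coding symbol.  An *intergenic* lncRNA is
additionally required to lie strictly more than 5 kb from the nearest
protein-coding gene on either side, measured between gene spans (outermost
transcript boundaries).

All coordinates are 0-based half-open internally; GTF (1-based, closed) is
converted on read and write.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: transcript biotypes that qualify a gene as a lncRNA when they are the
#: only biotypes the gene produces
LNCRNA_BIOTYPES = frozenset(
    {"antisense", "lincRNA", "non_coding", "processed_transcript"}
)

DEFAULT_MIN_MATURE_LENGTH = 200  # nt
DEFAULT_MIN_INTERGENIC_DISTANCE = 5000  # bp, strict inequality


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    biotype: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 0-based half-open

    @property
    def mature_length(self) -> int:
        """Summed exon length in nt (spliced transcript length)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    """One gene: identity, biotype, strand and exon structure."""

    gene_id: str
    symbol: str
    biotype: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        for t in self.transcripts:
            prev_end = -1
            for s, e in t.exons:
                if s >= e:
                    raise AnnotationError(
                        f"{self.gene_id}/{t.transcript_id}: empty exon [{s},{e})"
                    )
                if s < prev_end:
                    raise AnnotationError(
                        f"{self.gene_id}/{t.transcript_id}: exons overlap or unsorted"
                    )
                prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span covering all exons of all transcripts."""
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def mature_lengths(self) -> tuple[int, ...]:
        return tuple(t.mature_length for t in self.transcripts)

    @property
    def union_exon_length(self) -> int:
        """Length of the union of exonic bases across all transcripts (nt)."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total


@dataclass
class GeneAnnotation:
    """A set of gene models plus per-gene classification flags."""

    genes: list[GeneModel]
    is_lncrna: dict[str, bool] = field(default_factory=dict)
    is_intergenic_lncrna: dict[str, bool] = field(default_factory=dict)
    coding_symbol_blacklist: frozenset[str] = frozenset()

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise AnnotationError("duplicate gene_ids in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def is_coding(self, gene_id: str) -> bool:
        g = self.gene(gene_id)
        return any(t.biotype == "protein_coding" for t in g.transcripts)

    @property
    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if self.is_coding(g.gene_id)]

    @property
    def lncrna_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if self.is_lncrna.get(g.gene_id, False)]

    @property
    def intergenic_lncrna_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if self.is_intergenic_lncrna.get(g.gene_id, False)]

    def gene_class(self, gene_id: str) -> str:
        """'coding', 'lncRNA' or 'other' (pseudogenes etc. pass unflagged)."""
        if self.is_coding(gene_id):
            return "coding"
        if self.is_lncrna.get(gene_id, False):
            return "lncRNA"
        return "other"

    def gene_lengths(self) -> dict[str, int]:
        """Union exon length per gene, the length used for RPKM."""
        return {g.gene_id: g.union_exon_length for g in self.genes}


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, val = chunk.split(" ", 1)
        except ValueError:
            raise AnnotationError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gene_models(path, blacklist: set[str] | frozenset[str] = frozenset()) -> GeneAnnotation:
    """Read a GTF file into a :class:`GeneAnnotation`.

    Exon records are grouped into transcripts and genes by their
    ``gene_id``/``transcript_id`` attributes.  Genes whose id maps to more
    than one chromosome or strand (ambiguous genome mapping) are dropped
    with a warning.  Malformed records raise :class:`AnnotationError`
    naming the offending line.
    """
    # gene_id -> transcript_id -> (biotype, [exons]); track gene meta
    exon_map: dict[str, dict[str, tuple[str, list]]] = {}
    gene_meta: dict[str, dict] = {}
    ambiguous: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr_raw = fields
            if feature != "exon":
                continue
            try:
                start_i = int(start) - 1  # GTF is 1-based closed
                end_i = int(end)
            except ValueError:
                raise AnnotationError(f"line {lineno}: non-integer coordinates")
            if start_i < 0 or start_i >= end_i:
                raise AnnotationError(f"line {lineno}: invalid interval {start}-{end}")
            attrs = _parse_gtf_attributes(attr_raw, lineno)
            for req in ("gene_id", "transcript_id"):
                if req not in attrs:
                    raise AnnotationError(f"line {lineno}: missing attribute {req}")
            gid = attrs["gene_id"]
            meta = gene_meta.setdefault(
                gid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "symbol": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_type", attrs.get("gene_biotype", "")),
                },
            )
            if meta["chrom"] != chrom or meta["strand"] != strand:
                ambiguous.add(gid)
                continue
            tid = attrs["transcript_id"]
            tx_biotype = attrs.get(
                "transcript_type", attrs.get("transcript_biotype", meta["biotype"])
            )
            exon_map.setdefault(gid, {}).setdefault(tid, (tx_biotype, []))[1].append(
                (start_i, end_i)
            )

    for gid in ambiguous:
        log.warning("gene %s maps to multiple loci; removed", gid)
        exon_map.pop(gid, None)

    genes = []
    for gid, tx_map in exon_map.items():
        meta = gene_meta[gid]
        transcripts = tuple(
            Transcript(tid, biotype, tuple(sorted(exons)))
            for tid, (biotype, exons) in sorted(tx_map.items())
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=meta["symbol"],
                biotype=meta["biotype"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                transcripts=transcripts,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return GeneAnnotation(genes=genes, coding_symbol_blacklist=frozenset(blacklist))


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write exon records as GTF 2.2 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'gene_type "{g.biotype}"; transcript_type "{t.biotype}"; '
                        f'gene_name "{g.symbol}";'
                    )
                    fh.write(
                        f"{g.chrom}\tlncfocal\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )


def write_bed6(genes: list[GeneModel], path) -> None:
    """Write gene spans as BED6 (name=gene_id, score=0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            s, e = g.span
            fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_lncrnas(
    annotation: GeneAnnotation,
    min_length: int = DEFAULT_MIN_MATURE_LENGTH,
) -> GeneAnnotation:
    """Flag lncRNA genes in place and return the annotation.

    A gene is a lncRNA iff every transcript biotype is one of
    ``antisense``, ``lincRNA``, ``non_coding``, ``processed_transcript``,
    every mature transcript length is >= ``min_length`` nt, and the gene
    symbol does not match the coding-symbol blacklist (case-insensitive).
    Idempotent.
    """
    blacklist = {s.lower() for s in annotation.coding_symbol_blacklist}
    for g in annotation.genes:
        ok = (
            all(t.biotype in LNCRNA_BIOTYPES for t in g.transcripts)
            and all(length >= min_length for length in g.mature_lengths)
            and g.symbol.lower() not in blacklist
        )
        annotation.is_lncrna[g.gene_id] = ok
        if not ok:
            annotation.is_intergenic_lncrna[g.gene_id] = False
    return annotation


@dataclass(frozen=True)
class NeighborReport:
    """Nearest coding genes genomically left/right of a query gene.

    Distances are gap sizes in bp (0 when overlapping); ``None`` neighbor
    means no coding gene exists on that side of the chromosome.  The
    ``five_prime``/``three_prime`` aliases reinterpret left/right according
    to the query gene's strand.
    """

    left: GeneModel | None
    right: GeneModel | None
    left_distance: float  # inf when absent
    right_distance: float

    @property
    def five_prime(self):
        return self.left if self._plus else self.right

    @property
    def three_prime(self):
        return self.right if self._plus else self.left

    @property
    def min_distance(self) -> float:
        return min(self.left_distance, self.right_distance)

    # strand captured at construction
    _plus: bool = True


def nearest_coding_neighbors(
    gene: GeneModel | str, annotation: GeneAnnotation
) -> NeighborReport:
    """Nearest protein-coding gene on each side of ``gene``'s span.

    Distance is the gap between gene spans: 0 if the spans overlap,
    ``inf`` when no coding gene lies on that side of the chromosome.
    """
    if isinstance(gene, str):
        gene = annotation.gene(gene)
    elif gene.gene_id not in annotation:
        raise KeyError(f"gene {gene.gene_id!r} not in annotation")
    gs, ge = gene.span
    left = right = None
    left_d = right_d = math.inf
    for cg in annotation.coding_genes:
        if cg.chrom != gene.chrom or cg.gene_id == gene.gene_id:
            continue
        cs, ce = cg.span
        if ce > gs and cs < ge:  # spans overlap: gap 0, counted on both sides
            if left_d > 0:
                left, left_d = cg, 0.0
            if right_d > 0:
                right, right_d = cg, 0.0
        elif ce <= gs:
            d = float(gs - ce)
            if d < left_d:
                left, left_d = cg, d
        elif cs >= ge:
            d = float(cs - ge)
            if d < right_d:
                right, right_d = cg, d
    return NeighborReport(
        left=left, right=right, left_distance=left_d, right_distance=right_d,
        _plus=(gene.strand == "+"),
    )


def intergenic_subset(
    annotation: GeneAnnotation,
    min_distance: int = DEFAULT_MIN_INTERGENIC_DISTANCE,
) -> GeneAnnotation:
    """Flag intergenic lncRNAs: lncRNAs strictly more than ``min_distance``
    bp from the nearest coding gene on both sides (absent neighbors count
    as infinitely far).  Requires :func:`classify_lncrnas` first.
    """
    if not annotation.is_lncrna:
        raise AnnotationError("classify_lncrnas must be applied first")
    for g in annotation.genes:
        if not annotation.is_lncrna.get(g.gene_id, False):
            annotation.is_intergenic_lncrna[g.gene_id] = False
            continue
        rep = nearest_coding_neighbors(g, annotation)
        annotation.is_intergenic_lncrna[g.gene_id] = rep.min_distance > min_distance
    return annotation
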