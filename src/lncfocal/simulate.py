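"""Synthetic tumor cohorts with planted copy-number and expression structure.

The generator emulates the statistical structure of an integrated tumor
profiling study: a toy genome annotation with protein-coding genes and
interleaved lncRNAs (including one intergenic focal-target lncRNA sitting
55/65 kb from its coding neighbors, and antisense lncRNAs overlapping
coding hosts); a cohort of tumors partitioned into four expression
subtypes; per-sample segmented log2 copy-number with arm-level broad
gains and rare narrow (50-120 kb) focal amplicons centered on the target
lncRNA; and negative-binomial read counts in which

    E[count(g, s)] = library_s * weight(g, s) / sum_g weight(g, s)
    weight(g, s)  = (length_g / 1000) * 2^(b_g + k * CNA(g, s) + effects)

with a log-normal per-gene baseline b_g (lncRNAs offset far below coding
genes), a per-gene per-tumor log-normal biological variability term on
top of the negative-binomial counting noise (inter-tumor heterogeneity
dominates counting noise in real cohorts and sets a realistic
effect-to-noise ratio for the planted signals), a dosage slope k
coupling expression to copy number, planted
subtype-specific induction/repression of selected lncRNAs, and an extra
transcriptional-activation term for the focal target in focally
amplified tumors (copy-number gain alone does not explain the strong
induction seen at such loci).  A truth table records every planted fact
for parameter-recovery tests.

All randomness flows from one seed through named sub-streams, so a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GeneAnnotation,
    GeneModel,
    Transcript,
    classify_lncrnas,
    intergenic_subset,
    read_gene_models,
    write_gtf,
)
from .cn import SegmentSet, read_segments, write_segments
from .expression import ExpressionMatrix

DEFAULT_SUBTYPES = ("immunoreactive", "differentiated", "proliferative", "mesenchymal")

# focal-target geometry: gaps to the coding neighbors (bp); the resulting
# intergenic space (gaps + target span) is ~128 kb
FOCAL_UP_GAP = 55_000
FOCAL_DOWN_GAP = 65_000
FOCAL_GENE_SPAN = 8_000


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a cohort of 400 tumors in four equally likely
    expression subtypes over a two-chromosome toy genome with ~2,000
    genes; lncRNA baselines sit ~6.5 log2 units below coding genes so
    that far fewer lncRNAs than coding genes ever exceed 1 RPKM; a broad
    gain of +0.5 log2 covers the arm carrying the focal target in 40% of
    tumors, while 4% of tumors carry a narrow 50-120 kb amplicon of
    +0.6-1.5 log2 centered on the target.
    """

    n_samples: int = 400
    subtype_names: tuple[str, ...] = DEFAULT_SUBTYPES
    subtype_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    n_coding_genes: int = 1500
    n_lncrna_genes: int = 500
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 45_000_000, "chr2": 35_000_000}
    )
    baseline_log2_mean: float = -2.0
    baseline_log2_sd: float = 4.0
    lncrna_log2_expression_offset: float = -6.5
    dosage_slope: float = 1.0
    nb_dispersion: float = 0.2
    biological_log2_sd: float = 1.25
    n_signature_genes_per_subtype: int = 15
    signature_log2_effect: float = 2.0
    focal_target_gene: str = "LNC_TARGET"
    focal_frequency: float = 0.04
    focal_amplitude_range: tuple[float, float] = (0.6, 1.5)
    focal_width_range: tuple[int, int] = (50_000, 120_000)
    focal_activation_log2: float = 4.0
    focal_partial_neighbor_prob: float = 0.1
    broad_gain_frequency: float = 0.4
    broad_amplitude: float = 0.5
    segment_noise_sd: float = 0.05
    library_size_range: tuple[int, int] = (20_000_000, 80_000_000)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1")
        if len(self.subtype_proportions) != len(self.subtype_names):
            raise ConfigurationError("one proportion per subtype name")
        for name in ("n_samples", "n_coding_genes", "n_lncrna_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        intergenic_space = FOCAL_UP_GAP + FOCAL_DOWN_GAP + FOCAL_GENE_SPAN
        if self.focal_width_range[1] > intergenic_space:
            raise ConfigurationError(
                "focal_width_range does not fit the intergenic space around "
                f"the focal target ({intergenic_space} bp)"
            )
        if self.focal_width_range[0] < FOCAL_GENE_SPAN:
            raise ConfigurationError("amplicon narrower than the focal gene")
        if not (0 <= self.focal_frequency <= 1 and 0 <= self.broad_gain_frequency <= 1):
            raise ConfigurationError("frequencies must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named child generators; stable when one component's draw count
        changes."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ["annotation", "labels", "segments", "counts", "misc"]
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticCohort:
    config: SimConfig
    annotation: GeneAnnotation
    labels: pd.Series                 # sample -> subtype
    segments: SegmentSet
    counts: ExpressionMatrix
    truth: dict
    true_cna: pd.DataFrame            # genes x samples, generative CNA


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    symbol: str,
    biotype: str,
    chrom: str,
    strand: str,
    start: int,
    length: int,
) -> GeneModel:
    """One gene with 1-2 transcripts of 2-3 exons filling [start, start+length)."""
    n_tx = int(rng.integers(1, 3))
    transcripts = []
    for ti in range(n_tx):
        n_ex = int(rng.integers(2, 4))
        # alternate exon/intron pieces with bounded-ratio random lengths
        props = rng.random(2 * n_ex - 1) + 0.5
        props /= props.sum()
        pieces = np.maximum((props * length).astype(int), 1)
        pos = start
        exons = []
        for k, piece in enumerate(pieces):
            if k % 2 == 0:
                exons.append((pos, pos + int(piece)))
            pos += int(piece)
        transcripts.append(Transcript(f"{gene_id}.t{ti + 1}", biotype, tuple(exons)))
    return GeneModel(
        gene_id=gene_id, symbol=symbol, biotype=biotype, chrom=chrom,
        strand=strand, transcripts=tuple(transcripts),
    )


def generate_annotation(config: SimConfig) -> GeneAnnotation:
    """Toy genome annotation with the focal target planted intergenic.

    Coding genes are placed non-overlapping with random gaps; lncRNAs are
    interleaved (mostly lincRNAs, some antisense genes nested inside
    coding hosts).  The focal target lncRNA sits mid-chr1 with its coding
    neighbors 55 kb upstream and 65 kb downstream, so it survives the
    >5 kb intergenic filter by a wide margin.  Raises
    :class:`ConfigurationError` when the genome cannot hold the requested
    gene count.
    """
    config.validate()
    rng = config.streams()["annotation"]
    chroms = list(config.chrom_lengths)
    if not chroms:
        raise ConfigurationError("chrom_lengths is empty")
    total_len = sum(config.chrom_lengths.values())
    n_total = config.n_coding_genes + config.n_lncrna_genes

    # per-chromosome gene budget, proportional to length
    budget = {
        c: int(round(n_total * config.chrom_lengths[c] / total_len)) for c in chroms
    }
    budget[chroms[0]] += n_total - sum(budget.values())

    # focal block geometry on the first chromosome
    focal_chrom = chroms[0]
    l1 = config.chrom_lengths[focal_chrom]
    neighbor_len = 20_000
    block_start = int(l1 * 0.55)
    up_start = block_start
    up_end = up_start + neighbor_len
    target_start = up_end + FOCAL_UP_GAP
    target_end = target_start + FOCAL_GENE_SPAN
    down_start = target_end + FOCAL_DOWN_GAP
    down_end = down_start + neighbor_len
    if down_end > l1:
        raise ConfigurationError("first chromosome too short for the focal block")

    genes: list[GeneModel] = []
    coding_left = config.n_coding_genes - 2  # two neighbors placed explicitly
    lnc_left = config.n_lncrna_genes - 1     # the focal target
    if coding_left < 0 or lnc_left < 0:
        raise ConfigurationError("need at least 2 coding and 1 lncRNA gene")
    n_pc = n_lnc = 0
    antisense_placed = 0

    genes.append(
        _make_gene(rng, "PC_UP", "UPNB1", "protein_coding", focal_chrom, "+",
                   up_start, neighbor_len)
    )
    genes.append(
        _make_gene(rng, config.focal_target_gene, config.focal_target_gene,
                   "lincRNA", focal_chrom, "+", target_start, FOCAL_GENE_SPAN)
    )
    genes.append(
        _make_gene(rng, "PC_DOWN", "DNNB1", "protein_coding", focal_chrom, "-",
                   down_start, neighbor_len)
    )

    lnc_biotypes = np.array(["lincRNA", "antisense", "processed_transcript", "non_coding"])
    lnc_weights = np.array([0.70, 0.10, 0.12, 0.08])

    cursors: dict[str, int] = {}
    for chrom in chroms:
        n_here = budget[chrom]
        if chrom == focal_chrom:
            n_here = max(0, n_here - 3)
        clen = config.chrom_lengths[chrom]
        # reserved focal block plus a guard so neighbors stay the nearest genes
        reserved = (up_start - 10_000, down_end + 10_000) if chrom == focal_chrom else None
        cursor = 1_000
        last_coding: GeneModel | None = None
        placed = 0
        # scale gaps so the genes spread over the whole chromosome (and the
        # broad-gain arm carries its share of genes)
        mean_gap = max(2_000.0, (clen - n_here * 5_000 - 2_000) / max(n_here, 1))
        while placed < n_here and (coding_left + lnc_left) > 0:
            want_coding = rng.random() < coding_left / max(coding_left + lnc_left, 1)
            if coding_left == 0:
                want_coding = False
            if lnc_left == 0:
                want_coding = True
            if want_coding:
                length = int(rng.integers(2_000, 8_001))
            else:
                length = int(rng.integers(1_000, 6_001))
            gap = int(rng.uniform(0.5 * mean_gap, 1.5 * mean_gap))
            start = cursor + gap
            if reserved and start < reserved[1] and start + length > reserved[0]:
                cursor = reserved[1]
                continue
            if start + length > clen - 1_000:
                break  # chromosome full
            strand = "+" if rng.random() < 0.5 else "-"
            if want_coding:
                n_pc += 1
                g = _make_gene(rng, f"PC{n_pc:05d}", f"CODG{n_pc}", "protein_coding",
                               chrom, strand, start, length)
                last_coding = g
                coding_left -= 1
                cursor = start + length
            else:
                n_lnc += 1
                biotype = str(rng.choice(lnc_biotypes, p=lnc_weights))
                if antisense_placed == 0 and last_coding is not None:
                    biotype = "antisense"  # guarantee one antisense-overlapping gene
                if biotype == "antisense" and last_coding is not None:
                    host_s, host_e = last_coding.span
                    a_len = min(length, (host_e - host_s) - 200)
                    a_start = host_s + 100
                    a_strand = "-" if last_coding.strand == "+" else "+"
                    g = _make_gene(rng, f"LNC{n_lnc:05d}", f"LNCG{n_lnc}", "antisense",
                                   chrom, a_strand, a_start, max(a_len, 600))
                    antisense_placed += 1
                    # nested inside the host: cursor does not advance
                else:
                    if biotype == "antisense":
                        biotype = "lincRNA"
                    g = _make_gene(rng, f"LNC{n_lnc:05d}", f"LNCG{n_lnc}", biotype,
                                   chrom, strand, start, length)
                    cursor = start + length
                lnc_left -= 1
            genes.append(g)
            placed += 1
        cursors[chrom] = cursor

    # dense second pass: the scaled gaps are stochastic, so a chromosome can
    # run out of room before meeting its budget; pack any remainder tightly
    for chrom in chroms:
        clen = config.chrom_lengths[chrom]
        reserved = (up_start - 10_000, down_end + 10_000) if chrom == focal_chrom else None
        cursor = cursors[chrom]
        while (coding_left + lnc_left) > 0:
            want_coding = coding_left >= lnc_left
            length = int(rng.integers(2_000, 8_001)) if want_coding else int(
                rng.integers(1_000, 6_001))
            start = cursor + int(rng.integers(2_000, 8_001))
            if reserved and start < reserved[1] and start + length > reserved[0]:
                cursor = reserved[1]
                continue
            if start + length > clen - 1_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            if want_coding:
                n_pc += 1
                genes.append(_make_gene(rng, f"PC{n_pc:05d}", f"CODG{n_pc}",
                                        "protein_coding", chrom, strand, start, length))
                coding_left -= 1
            else:
                n_lnc += 1
                genes.append(_make_gene(rng, f"LNC{n_lnc:05d}", f"LNCG{n_lnc}",
                                        "lincRNA", chrom, strand, start, length))
                lnc_left -= 1
            cursor = start + length

    if coding_left > 0 or lnc_left > 0:
        raise ConfigurationError(
            f"layout infeasible: {coding_left} coding and {lnc_left} lncRNA genes "
            "did not fit in chrom_lengths"
        )

    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    annotation = GeneAnnotation(genes=genes)
    classify_lncrnas(annotation)
    intergenic_subset(annotation)
    return annotation


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _baseline_segments(rng, clen, noise_sd, arm_start=None, broad=False, broad_amp=0.0):
    segs = []
    pos = 0
    while pos < clen:
        end = min(pos + int(rng.uniform(3e6, 10e6)), clen)
        if arm_start is not None and pos < arm_start < end:
            end = arm_start  # force a breakpoint at the arm boundary
        amp = rng.normal(0.0, noise_sd)
        if broad and arm_start is not None and pos >= arm_start:
            amp += broad_amp
        segs.append([pos, end, amp])
        pos = end
    return segs


def _insert_amplicon(segs, a_start, a_end, delta):
    """Overlay [a_start, a_end) with amplitude base+delta, splitting segments."""
    center = (a_start + a_end) // 2
    base = next(a for s, e, a in segs if s <= center < e)
    out = []
    for s, e, a in segs:
        if e <= a_start or s >= a_end:
            out.append([s, e, a])
            continue
        if s < a_start:
            out.append([s, a_start, a])
        if e > a_end:
            out.append([a_end, e, a])
    out.append([a_start, a_end, base + delta])
    out.sort(key=lambda x: x[0])
    return out


def _gene_cna_from_segments(genes, seg_by_chrom):
    """Generative per-gene CNA: min amplitude over overlapping segments."""
    out = np.full(len(genes), np.nan)
    for i, g in enumerate(genes):
        segs = seg_by_chrom.get(g.chrom)
        if segs is None:
            continue
        gs, ge = g.span
        amps = [a for s, e, a in segs if s < ge and e > gs]
        if amps:
            out[i] = min(amps)
    return out


def generate_cohort(config: SimConfig, annotation: GeneAnnotation) -> SyntheticCohort:
    """Cohort of labeled tumors: segments, counts and a truth table."""
    config.validate()
    streams = config.streams()
    samples = [f"TUMOR_{i + 1:04d}" for i in range(config.n_samples)]
    genes = annotation.genes
    gene_ids = [g.gene_id for g in genes]
    target = annotation.gene(config.focal_target_gene)

    # --- labels -----------------------------------------------------------
    rng_l = streams["labels"]
    labels = pd.Series(
        rng_l.choice(list(config.subtype_names), size=config.n_samples,
                     p=list(config.subtype_proportions)),
        index=pd.Index(samples, name="sample"), name="subtype",
    )

    # --- segments ---------------------------------------------------------
    rng_s = streams["segments"]
    focal_chrom = target.chrom
    arm_start = int(config.chrom_lengths[focal_chrom] * 0.4)
    broad_mask = rng_s.random(config.n_samples) < config.broad_gain_frequency
    focal_mask = rng_s.random(config.n_samples) < config.focal_frequency

    up_end = annotation.gene("PC_UP").span[1] if "PC_UP" in annotation else None
    down_start = annotation.gene("PC_DOWN").span[0] if "PC_DOWN" in annotation else None
    gs, ge = target.span

    seg_rows = []
    cna = np.full((len(genes), len(samples)), np.nan)
    for j, sample in enumerate(samples):
        seg_by_chrom = {}
        for chrom, clen in config.chrom_lengths.items():
            if chrom == focal_chrom:
                segs = _baseline_segments(
                    rng_s, clen, config.segment_noise_sd, arm_start=arm_start,
                    broad=bool(broad_mask[j]), broad_amp=config.broad_amplitude,
                )
            else:
                segs = _baseline_segments(rng_s, clen, config.segment_noise_sd)
            seg_by_chrom[chrom] = segs
        if focal_mask[j]:
            width = int(rng_s.integers(*config.focal_width_range))
            lo = max(up_end if up_end is not None else 0, ge - width)
            focal_clen = config.chrom_lengths[focal_chrom]
            hi = min(gs, (down_start if down_start is not None else focal_clen) - width)
            a_start = int(rng_s.integers(lo, max(lo + 1, hi + 1)))
            a_end = a_start + width
            if (
                down_start is not None
                and rng_s.random() < config.focal_partial_neighbor_prob
            ):
                # amplicon extends only partially into the downstream neighbor
                down_len = annotation.gene("PC_DOWN").span[1] - down_start
                a_end = down_start + int(rng_s.uniform(0.1, 0.4) * down_len)
            delta = rng_s.uniform(*config.focal_amplitude_range)
            seg_by_chrom[focal_chrom] = _insert_amplicon(
                seg_by_chrom[focal_chrom], a_start, a_end, delta
            )
        cna[:, j] = _gene_cna_from_segments(genes, seg_by_chrom)
        for chrom in config.chrom_lengths:
            for s, e, a in seg_by_chrom[chrom]:
                seg_rows.append((sample, chrom, int(s), int(e), round(float(a), 6)))

    segments = SegmentSet(
        pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end", "seg_mean"])
    )

    # --- planted expression effects --------------------------------------
    rng_c = streams["counts"]
    is_lnc = np.array([annotation.is_lncrna.get(g, False) for g in gene_ids])
    baselines = rng_c.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                             size=len(genes))
    baselines[is_lnc] += config.lncrna_log2_expression_offset

    # signature genes: drawn from the better-expressed half of lncRNAs so the
    # planted effects are observable above the count floor
    lnc_idx = np.flatnonzero(is_lnc & (np.array(gene_ids) != config.focal_target_gene))
    expressed = lnc_idx[baselines[lnc_idx] >= np.median(baselines[lnc_idx])]
    n_sig = config.n_signature_genes_per_subtype * len(config.subtype_names)
    if n_sig > len(expressed):
        raise ConfigurationError("not enough expressed lncRNAs for signature genes")
    sig_idx = rng_c.choice(expressed, size=n_sig, replace=False)
    signature_truth = []
    effect = np.zeros((len(genes), len(samples)))
    label_arr = labels.to_numpy()
    for k, gi in enumerate(sig_idx):
        subtype = config.subtype_names[k % len(config.subtype_names)]
        direction = "induced" if (k // len(config.subtype_names)) % 3 != 2 else "repressed"
        sign = 1.0 if direction == "induced" else -1.0
        effect[gi, label_arr == subtype] += sign * config.signature_log2_effect
        signature_truth.append(
            {"gene_id": gene_ids[gi], "subtype": subtype, "direction": direction}
        )

    target_i = gene_ids.index(config.focal_target_gene)
    effect[target_i, focal_mask] += config.focal_activation_log2

    # --- counts -----------------------------------------------------------
    lengths = np.array([g.union_exon_length for g in genes], dtype=float)
    cna_filled = np.nan_to_num(cna, nan=0.0)
    log2_w = (
        baselines[:, None] + config.dosage_slope * cna_filled + effect
        + np.log2(lengths / 1000.0)[:, None]
    )
    if config.biological_log2_sd > 0:
        # inter-tumor biological variability beyond counting noise
        log2_w = log2_w + rng_c.normal(
            0.0, config.biological_log2_sd, size=log2_w.shape
        )
    w = np.exp2(log2_w)
    lib_targets = rng_c.integers(
        config.library_size_range[0], config.library_size_range[1] + 1,
        size=len(samples),
    ).astype(float)
    mu = w / w.sum(axis=0, keepdims=True) * lib_targets[None, :]
    if config.nb_dispersion == 0:
        counts = np.rint(mu).astype(np.int64)  # deterministic limiting case
    else:
        lam = rng_c.gamma(1.0 / config.nb_dispersion, mu * config.nb_dispersion)
        counts = rng_c.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(
        counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples
    )
    expr = ExpressionMatrix(
        counts=counts_df,
        gene_lengths=pd.Series(lengths, index=gene_ids),
    )

    truth = {
        "signature_genes": signature_truth,
        "focal_samples": [s for s, f in zip(samples, focal_mask) if f],
        "broad_samples": [s for s, b in zip(samples, broad_mask) if b],
        "dosage_slope": {g: config.dosage_slope for g in gene_ids},
        "baseline_log2": {g: float(b) for g, b in zip(gene_ids, baselines)},
        "focal_target_gene": config.focal_target_gene,
        "focal_neighbors": {"upstream": "PC_UP", "downstream": "PC_DOWN"},
    }
    return SyntheticCohort(
        config=config,
        annotation=annotation,
        labels=labels,
        segments=segments,
        counts=expr,
        truth=truth,
        true_cna=pd.DataFrame(cna, index=gene_ids, columns=samples),
    )


def simulate(config: SimConfig | None = None) -> SyntheticCohort:
    """Convenience wrapper: annotation plus cohort from one config."""
    config = config or SimConfig()
    annotation = generate_annotation(config)
    return generate_cohort(config, annotation)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "annotation": "annotation.gtf",
    "segments": "segments.seg",
    "counts": "counts.tsv",
    "labels": "labels.tsv",
    "truth": "truth.json",
}


def write_fixtures(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write the cohort as plain-text fixtures; deterministic bytes.

    Emits GTF annotation, SEG-style segments, a counts TSV, a labels TSV
    and the truth JSON.  Reading them back reproduces the in-memory
    objects.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in FIXTURE_FILES.items()}
    write_gtf(cohort.annotation, paths["annotation"])
    write_segments(cohort.segments, paths["segments"])
    cohort.counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    cohort.labels.to_frame().to_csv(paths["labels"], sep="\t", index_label="sample")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_fixtures(directory):
    """Read fixtures written by :func:`write_fixtures`.

    Returns ``(annotation, segments, expression, labels, truth)`` with the
    annotation re-classified (lncRNA and intergenic flags repopulated).
    """
    import os

    paths = {k: os.path.join(directory, v) for k, v in FIXTURE_FILES.items()}
    annotation = read_gene_models(paths["annotation"])
    classify_lncrnas(annotation)
    intergenic_subset(annotation)
    segments = read_segments(paths["segments"])
    counts = pd.read_csv(paths["counts"], sep="\t", index_col="gene_id")
    labels = pd.read_csv(paths["labels"], sep="\t", index_col="sample")["subtype"]
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    lengths = pd.Series({g.gene_id: g.union_exon_length for g in annotation.genes})
    expr = ExpressionMatrix(counts=counts, gene_lengths=lengths.reindex(counts.index))
    return annotation, segments, expr, labels, truth
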