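import numpy as np
import pandas as pd
import pytest

from lncfocal import (
    GeneAnnotation,
    GeneModel,
    SimConfig,
    Transcript,
    assign_gene_cna,
    generate_annotation,
    generate_cohort,
)


def make_gene(
    gene_id,
    chrom="chr1",
    start=0,
    exons=None,
    biotype="protein_coding",
    strand="+",
    symbol=None,
    n_exons=1,
    length=1000,
):
    """Compact GeneModel builder for unit tests (single transcript)."""
    if exons is None:
        step = length // n_exons
        exons = tuple((start + i * step, start + i * step + max(step - 50, 1))
                      for i in range(n_exons))
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        transcripts=(Transcript(f"{gene_id}.t1", biotype, tuple(exons)),),
    )


def make_annotation(*genes, blacklist=frozenset()):
    return GeneAnnotation(genes=list(genes), coding_symbol_blacklist=frozenset(blacklist))


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def cohort400(default_config):
    """The full-size synthetic cohort (400 tumors, 2,000 genes, fixed seed)."""
    annotation = generate_annotation(default_config)
    return generate_cohort(default_config, annotation)


@pytest.fixture(scope="session")
def cn400(cohort400):
    """Gene-level copy-number matrix for the full-size cohort."""
    return assign_gene_cna(cohort400.segments, cohort400.annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for tests that only need structure, not power."""
    config = SimConfig(
        n_samples=60,
        n_coding_genes=120,
        n_lncrna_genes=60,
        chrom_lengths={"chr1": 12_000_000, "chr2": 8_000_000},
        n_signature_genes_per_subtype=4,
        seed=11,
    )
    annotation = generate_annotation(config)
    return generate_cohort(config, annotation)
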