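"""Subtype-selective lncRNA signatures and centroid classification.

Tumor expression subtypes (for high-grade serous ovarian carcinoma:
immunoreactive, differentiated, proliferative, mesenchymal) are taken as
given labels.  Subtype-associated genes are found on a discovery half of
the cohort by a one-vs-rest two-sample t statistic on log-scale
expression, keeping genes with |t| strictly above 4 in exactly one
subtype (genes passing in several subtypes are ambiguous and dropped;
genes with more than 50% zero-count values are excluded up front).

Classification scores each tumor and subtype as

    score = mean(z of the subtype's induced genes)
          - mean(z of the subtype's repressed genes)

on z-score normalized log expression, predicting the highest-scoring
subtype.  Accuracy on a withheld validation half measures how well the
signatures generalize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_T_THRESHOLD = 4.0
DEFAULT_MISSING_FRACTION_MAX = 0.5
DEFAULT_N_PER_SET = 200


class SubtypeError(ValueError):
    pass


def split_cohort(
    samples: list[str],
    n_per_set: int = DEFAULT_N_PER_SET,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Random disjoint discovery/validation partition.

    The discovery set gets exactly ``n_per_set`` samples; all remaining
    samples form the validation set (an odd sample lands in validation).
    Deterministic for a fixed seed.
    """
    if len(samples) < n_per_set + 1:
        raise SubtypeError(
            f"need more than {n_per_set} samples to withhold a validation set"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    discovery = [samples[i] for i in sorted(order[:n_per_set])]
    validation = [samples[i] for i in sorted(order[n_per_set:])]
    return discovery, validation


def zscore(log_expr: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-gene z-score normalization over the given sample set.

    Uses the population standard deviation (ddof=0).  Genes with zero
    variance are flagged by an all-NaN row (excluded downstream).
    """
    sub = log_expr[samples] if samples is not None else log_expr
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mean, axis=0).div(sd, axis=0)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d constant genes flagged during z-scoring", int(degenerate.sum()))
        z.loc[degenerate] = np.nan
    return z


def subtype_t_statistics(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    counts: pd.DataFrame | None = None,
    missing_fraction_max: float = DEFAULT_MISSING_FRACTION_MAX,
    equal_var: bool = False,
) -> pd.DataFrame:
    """One-vs-rest t statistics per gene and subtype.

    ``labels`` maps sample -> subtype and must cover a subset of the
    expression columns; each subtype needs at least 2 samples.  When
    ``counts`` is given, genes whose zero-count fraction exceeds
    ``missing_fraction_max`` over the labeled samples are excluded.
    Welch's unequal-variance statistic by default; ``equal_var=True``
    selects the pooled-variance form.
    """
    samples = [s for s in labels.index if s in log_expr.columns]
    if not samples:
        raise SubtypeError("no labeled samples present in the expression matrix")
    labels = labels.loc[samples]
    expr = log_expr[samples]

    if counts is not None:
        zero_frac = (counts[samples] == 0).mean(axis=1)
        keep = zero_frac.reindex(expr.index) <= missing_fraction_max
        expr = expr.loc[keep]

    subtypes = list(dict.fromkeys(labels))
    values = expr.to_numpy(dtype=float)
    out = {}
    for subtype in subtypes:
        in_group = (labels == subtype).to_numpy()
        n1, n2 = int(in_group.sum()), int((~in_group).sum())
        if n1 < 2 or n2 < 2:
            raise SubtypeError(f"subtype {subtype!r} has fewer than 2 samples")
        x = values[:, in_group]
        y = values[:, ~in_group]
        m1, m2 = x.mean(axis=1), y.mean(axis=1)
        v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        if equal_var:
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(pooled * (1 / n1 + 1 / n2))
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[subtype] = (m1 - m2) / se
    return pd.DataFrame(out, index=expr.index)


@dataclass(frozen=True)
class SignatureGene:
    gene_id: str
    subtype: str
    direction: str  # "induced" | "repressed"
    t_statistic: float


def select_signature(
    t_values: pd.DataFrame,
    t_threshold: float = DEFAULT_T_THRESHOLD,
) -> list[SignatureGene]:
    """Genes with |t| strictly above the threshold in exactly one subtype.

    Genes passing the threshold in more than one subtype are ambiguous
    and not considered.  Direction is ``induced`` for positive t.
    """
    hits = t_values.abs() > t_threshold
    n_hits = hits.sum(axis=1)
    signatures = []
    for gene_id in t_values.index[n_hits == 1]:
        subtype = hits.columns[hits.loc[gene_id]][0]
        t = float(t_values.at[gene_id, subtype])
        signatures.append(
            SignatureGene(
                gene_id=gene_id,
                subtype=subtype,
                direction="induced" if t > 0 else "repressed",
                t_statistic=t,
            )
        )
    return signatures


def signatures_to_frame(signatures: list[SignatureGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.subtype, s.direction, s.t_statistic) for s in signatures],
        columns=["gene_id", "subtype", "direction", "t"],
    )


@dataclass
class ClassifierResult:
    scores: pd.DataFrame          # samples x subtypes
    predictions: pd.Series        # sample -> subtype
    ties: list[str]               # samples with an exact score tie
    accuracy: float | None = None


def classify_subtype(
    z_layer: pd.DataFrame,
    signatures: list[SignatureGene],
    subtype_order: list[str],
    labels: pd.Series | None = None,
) -> ClassifierResult:
    """Z-score centroid classifier from signature genes.

    Per sample and subtype: mean z over that subtype's induced genes minus
    mean z over its repressed genes (a direction with no genes present in
    the matrix contributes 0).  The prediction is the highest-scoring
    subtype; exact ties resolve to the first subtype in
    ``subtype_order`` and are flagged.  A subtype with no signature genes
    at all raises an error naming it.
    """
    by_subtype: dict[str, dict[str, list[str]]] = {
        s: {"induced": [], "repressed": []} for s in subtype_order
    }
    for sig in signatures:
        if sig.subtype in by_subtype and sig.gene_id in z_layer.index:
            by_subtype[sig.subtype][sig.direction].append(sig.gene_id)

    scores = pd.DataFrame(0.0, index=z_layer.columns, columns=subtype_order)
    for subtype in subtype_order:
        induced = by_subtype[subtype]["induced"]
        repressed = by_subtype[subtype]["repressed"]
        if not induced and not repressed:
            raise SubtypeError(f"subtype {subtype!r} has no signature genes")
        score = pd.Series(0.0, index=z_layer.columns)
        if induced:
            score = score + z_layer.loc[induced].mean(axis=0, skipna=True)
        if repressed:
            score = score - z_layer.loc[repressed].mean(axis=0, skipna=True)
        scores[subtype] = score

    values = scores.to_numpy()
    best = values.argmax(axis=1)  # argmax takes the first maximum in order
    predictions = pd.Series(
        [subtype_order[i] for i in best], index=scores.index, name="subtype"
    )
    max_per_row = values.max(axis=1, keepdims=True)
    ties = list(scores.index[(values == max_per_row).sum(axis=1) > 1])
    if ties:
        log.warning("%d samples with exact score ties", len(ties))

    accuracy = None
    if labels is not None:
        shared = [s for s in predictions.index if s in labels.index]
        accuracy = float((predictions.loc[shared] == labels.loc[shared]).mean())
    return ClassifierResult(
        scores=scores, predictions=predictions, ties=ties, accuracy=accuracy
    )
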