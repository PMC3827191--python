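"""Copy-number / expression dosage correlation, with stratification.

For each gene, the correlation across tumors between gene-level log2
copy-number amplitude and log2 RPKM measures the dosage effect of DNA
copy number on expression.  Coefficients are undefined (NaN, flagged)
when fewer than ``min_pairs`` samples carry both values or when either
variable is constant.  The stratified comparison restricts to genes that
are both appreciably expressed (max RPKM strictly above a threshold,
default 3) and recurrently altered (altered in strictly more than a
threshold number of samples, default 15), the regime in which dosage
coupling is detectable above measurement noise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cn import GeneCNMatrix

log = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 10
DEFAULT_RPKM_STRATUM_THRESHOLD = 3.0
DEFAULT_ALTERED_STRATUM_THRESHOLD = 15
HISTOGRAM_BIN_WIDTH = 0.05


class CorrelationError(ValueError):
    pass


def cn_expression_correlation(
    cn: GeneCNMatrix,
    log2_rpkm: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene correlation between copy-number amplitude and expression.

    Returns a DataFrame indexed by gene with columns ``r`` (NaN when
    undefined) and ``n_pairs``.  Only samples with a determined
    copy-number value enter each gene's computation.
    """
    if method not in ("pearson", "spearman"):
        raise CorrelationError(f"unknown method {method!r}")
    samples = [s for s in cn.samples if s in log2_rpkm.columns]
    if not samples:
        raise CorrelationError("no shared samples between copy number and expression")
    genes = [g for g in cn.genes if g in log2_rpkm.index]
    cn_m = cn.matrix.loc[genes, samples].to_numpy()
    ex_m = log2_rpkm.loc[genes, samples].to_numpy()

    r = np.full(len(genes), np.nan)
    n_pairs = np.zeros(len(genes), dtype=int)
    for i in range(len(genes)):
        mask = np.isfinite(cn_m[i]) & np.isfinite(ex_m[i])
        n = int(mask.sum())
        n_pairs[i] = n
        if n < min_pairs:
            continue
        x, y = cn_m[i, mask], ex_m[i, mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # constant variable: undefined, stays NaN
        if method == "pearson":
            r[i] = stats.pearsonr(x, y).statistic
        else:
            r[i] = stats.spearmanr(x, y).statistic
    return pd.DataFrame({"r": r, "n_pairs": n_pairs}, index=pd.Index(genes, name="gene_id"))


def stratify_correlations(
    result: pd.DataFrame,
    gene_classes: pd.Series,
    max_rpkm: pd.Series,
    altered_counts: pd.Series,
    rpkm_threshold: float = DEFAULT_RPKM_STRATUM_THRESHOLD,
    altered_threshold: int = DEFAULT_ALTERED_STRATUM_THRESHOLD,
) -> dict[str, dict]:
    """Summaries of the correlation distribution per gene class, overall
    and restricted to the expressed-and-recurrently-altered stratum.

    Strata use strict inequalities: max RPKM > ``rpkm_threshold`` and
    altered-sample count > ``altered_threshold``.  Returns a dict keyed by
    ``"<class>"`` and ``"<class>_stratified"``, each holding mean, median,
    n (genes with a defined coefficient) and histogram counts over bins of
    width 0.05 on [-1, 1].  Empty strata are omitted with a warning.
    """
    gene_classes = gene_classes.reindex(result.index)
    max_rpkm = max_rpkm.reindex(result.index)
    altered_counts = altered_counts.reindex(result.index)
    in_stratum = (max_rpkm > rpkm_threshold) & (altered_counts > altered_threshold)

    out: dict[str, dict] = {}
    for cls in gene_classes.dropna().unique():
        cls_mask = (gene_classes == cls).to_numpy()
        for name, mask in (
            (str(cls), cls_mask),
            (f"{cls}_stratified", cls_mask & in_stratum.to_numpy()),
        ):
            r = result.loc[mask, "r"].dropna()
            if r.empty:
                log.warning("stratum %s is empty; summary omitted", name)
                continue
            edges = np.arange(-1, 1 + HISTOGRAM_BIN_WIDTH, HISTOGRAM_BIN_WIDTH)
            hist, _ = np.histogram(r, bins=edges)
            out[name] = {
                "mean": float(r.mean()),
                "median": float(r.median()),
                "n": int(len(r)),
                "histogram": hist.tolist(),
                "bin_edges": edges.tolist(),
            }
    return out
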