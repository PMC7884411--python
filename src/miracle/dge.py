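"""Supervised differential expression between ICR-high and ICR-low tertiles.

Samples are split by the first and third tertile of the ICR enrichment
score (the middle tertile is excluded), and each gene is tested with a
two-sided Wilcoxon rank-sum test, high vs low. P-values are adjusted across
all tested genes with Benjamini-Hochberg. The default significance filter
keeps genes with log2 fold change > 1, p < 0.05 and FDR < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ContractError, DegenerateDataError
from .survival import bh_adjust
from .types import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

#: Combined group size at or below which the exact rank-sum null is used
#: (when a gene has no ties); above it, the normal approximation with tie
#: correction and continuity correction.
EXACT_MAX_N = 20


def tertile_groups(nes: pd.Series) -> tuple[list[str], list[str]]:
    """Split samples into the bottom and top tertile of a score.

    Samples are sorted ascending by score with ties broken by sample id
    (stable), low = first floor(N/3), high = last floor(N/3). If every score
    is equal the groups are defined purely by id order and a warning is
    emitted.
    """
    if len(nes) < 3:
        raise DegenerateDataError(f"need >= 3 samples for tertiles, got {len(nes)}")
    if nes.nunique() == 1:
        logger.warning("all scores identical; tertile groups defined by sample-id order")
    order = sorted(nes.index.astype(str), key=lambda s: (nes[s], s))
    k = len(order) // 3
    return order[:k], order[-k:]


def _log2fc(high: np.ndarray, low: np.ndarray, log_scale: bool, pseudocount: float) -> np.ndarray:
    mean_high = high.mean(axis=1)
    mean_low = low.mean(axis=1)
    if log_scale:
        return mean_high - mean_low
    return np.log2((mean_high + pseudocount) / (mean_low + pseudocount))


@dataclass(frozen=True)
class DEGThresholds:
    """Significance filter for differentially expressed genes."""

    log2fc: float = 1.0
    p: float = 0.05
    fdr: float = 0.1
    strict: bool = True  # strict '>' / '<' comparisons


def wilcoxon_de(
    expr: ExpressionMatrix,
    low_ids: list[str],
    high_ids: list[str],
    log_scale: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test, high vs low group.

    Returns a DEG table indexed by gene with columns ``log2fc``, ``p``,
    ``fdr`` and ``rank`` (1-based significance rank over all tested genes:
    ascending p, ties broken by descending \\|log2fc\\| then gene id).

    The exact enumeration null is used when the combined group size is at
    most 20 and the gene has no cross-group ties; otherwise the normal
    approximation with tie correction. Genes constant across both groups
    get p = 1.

    ``log_scale`` switches the fold change from the pseudocounted ratio of
    group means (for non-negative normalised counts) to the difference of
    means (for data already on a log scale).
    """
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ContractError("both groups need >= 2 samples")
    overlap = set(low_ids) & set(high_ids)
    if overlap:
        raise ContractError(f"groups overlap: {sorted(overlap)[:5]}")
    low = expr.subset_samples(list(low_ids)).values
    high = expr.subset_samples(list(high_ids)).values
    n_combined = low.shape[1] + high.shape[1]

    log2fc = _log2fc(high, low, log_scale, pseudocount)
    pvals = np.ones(expr.n_genes)
    constant = np.array(
        [np.unique(np.concatenate([high[i], low[i]])).size == 1 for i in range(expr.n_genes)]
    )
    testable = ~constant
    if n_combined <= EXACT_MAX_N:
        for i in np.flatnonzero(testable):
            combined = np.concatenate([high[i], low[i]])
            method = "exact" if np.unique(combined).size == combined.size else "asymptotic"
            pvals[i] = mannwhitneyu(high[i], low[i], alternative="two-sided", method=method).pvalue
    elif testable.any():
        res = mannwhitneyu(
            high[testable], low[testable], alternative="two-sided", method="asymptotic", axis=1
        )
        pvals[testable] = res.pvalue
    pvals = np.clip(pvals, 0.0, 1.0)

    fdr = bh_adjust(pvals)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "fdr": fdr},
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    order = sorted(range(len(table)), key=lambda i: (pvals[i], -abs(log2fc[i]), expr.gene_ids[i]))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return table


def filter_degs(
    table: pd.DataFrame,
    thresholds: DEGThresholds = DEGThresholds(),
    name: str = "DEGs",
) -> GeneSet | None:
    """Apply the significance filter; returns ``None`` when nothing passes."""
    t = thresholds
    if t.strict:
        mask = (table["log2fc"] > t.log2fc) & (table["p"] < t.p) & (table["fdr"] < t.fdr)
    else:
        mask = (table["log2fc"] >= t.log2fc) & (table["p"] <= t.p) & (table["fdr"] <= t.fdr)
    genes = table.index[mask].tolist()
    logger.info("%s: %d of %d genes pass the filter", name, len(genes), len(table))
    if not genes:
        return None
    return GeneSet(name=name, genes=tuple(genes))
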