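"""Single-sample gene-set enrichment via the Mann-Whitney-Wilcoxon gene-set test.

For one sample, genes are ranked by expression (ascending, midranks for
ties). With ``m`` genes inside the set, ``n`` outside, and ``T`` the sum of
within-set ranks, the Mann-Whitney statistic is

    U = m*n + m*(m+1)/2 - T

and the normalised enrichment score is

    NES = 1 - U / (m*n),

the probability that a randomly chosen in-set gene outranks a randomly
chosen out-set gene in this sample (ties counting one half). NES lies in
[0, 1] by construction and depends only on the within-sample ranking, so it
is invariant to any strictly increasing transform of the profile and needs
no cross-sample normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NoOverlapError
from .types import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """NES of one gene set in one sample, with the underlying rank sums."""

    sample_id: str
    set_name: str
    nes: float
    m: int
    n: int
    t_sum: float
    u_stat: float


def _nes_from_ranks(ranks: np.ndarray, in_set: np.ndarray) -> tuple[float, float, float, int, int]:
    m = int(in_set.sum())
    n = ranks.size - m
    t_sum = float(ranks[in_set].sum())
    u_stat = m * n + m * (m + 1) / 2.0 - t_sum
    nes = 1.0 - u_stat / (m * n)
    return nes, t_sum, u_stat, m, n


def mww_gst_nes(profile: pd.Series, geneset: GeneSet, sample_id: str | None = None) -> EnrichmentResult:
    """Score one expression profile against one gene set.

    Parameters
    ----------
    profile : per-gene expression for a single sample, indexed by gene symbol.
    geneset : the signature to score.

    Raises
    ------
    NoOverlapError
        If no signature gene is present in the profile, or every profile
        gene is in the set (no out-set genes to rank against).
    """
    genes = pd.Index([str(g).strip().upper() for g in profile.index])
    values = np.asarray(profile.to_numpy(), dtype=float)
    in_set = genes.isin(set(geneset.genes))
    m = int(in_set.sum())
    n = values.size - m
    name = sample_id if sample_id is not None else (profile.name or "sample")
    if m == 0:
        raise NoOverlapError(f"gene set {geneset.name!r} shares no genes with the profile")
    if n == 0:
        raise NoOverlapError(f"gene set {geneset.name!r} covers the whole profile; no out-set genes")
    if np.unique(values).size == 1:
        logger.warning("sample %s: degenerate profile (all values equal); NES = 0.5", name)
    ranks = rankdata(values)
    nes, t_sum, u_stat, m, n = _nes_from_ranks(ranks, in_set)
    return EnrichmentResult(str(name), geneset.name, nes, m, n, t_sum, u_stat)


def score_matrix(expr: ExpressionMatrix, sets: list[GeneSet]) -> pd.DataFrame:
    """Score every sample against every gene set.

    Returns a tidy frame with one row per (sample, set) and columns
    ``sample_id, set_name, nes, m, n, t_sum, u_stat``. Sets with zero
    overlap are skipped with a warning rather than failing the run; the
    per-set overlap counts are logged once.
    """
    ranks = rankdata(expr.values, axis=0)  # per-sample (column-wise) midranks
    genes = pd.Index(expr.gene_ids)
    records: list[dict] = []
    for gs in sets:
        in_set = np.asarray(genes.isin(set(gs.genes)))
        m = int(in_set.sum())
        n = expr.n_genes - m
        if m == 0 or n == 0:
            logger.warning("gene set %s skipped: overlap m=%d, out-set n=%d", gs.name, m, n)
            continue
        logger.info("gene set %s: %d/%d genes present in matrix", gs.name, m, len(gs))
        t_sum = ranks[in_set, :].sum(axis=0)
        u_stat = m * n + m * (m + 1) / 2.0 - t_sum
        nes = 1.0 - u_stat / (m * n)
        for j, sample in enumerate(expr.sample_ids):
            records.append(
                {
                    "sample_id": sample,
                    "set_name": gs.name,
                    "nes": float(nes[j]),
                    "m": m,
                    "n": n,
                    "t_sum": float(t_sum[j]),
                    "u_stat": float(u_stat[j]),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "set_name", "nes", "m", "n", "t_sum", "u_stat"]
    )


def nes_wide(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy score table to samples x sets of NES values."""
    wide = scores.pivot(index="sample_id", columns="set_name", values="nes")
    return wide.rename_axis(index="sample_id", columns=None)


def nes_series(expr: ExpressionMatrix, geneset: GeneSet) -> pd.Series:
    """Per-sample NES of one set, in the matrix's sample order."""
    scores = score_matrix(expr, [geneset])
    if scores.empty:
        raise NoOverlapError(f"gene set {geneset.name!r} shares no genes with the matrix")
    ser = scores.set_index("sample_id")["nes"]
    return ser.reindex(expr.sample_ids)
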