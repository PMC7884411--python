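"""Derive the IE- and ID-specific signature sets by exclusivity and rank difference.

Two DEG lists (one from the immune-enabled cohorts, one from the
immune-disabled cohorts) are reduced to their exclusive members; each
exclusive gene is then re-scored by the difference of its significance
ranks in the two *full* DEG tables,

    dR_IE = R_IE - R_ID        (IE list; most negative = most IE-specific)
    dR_ID = R_ID - R_IE        (ID list; symmetric)

so that genes significant in both analyses, which a hard cut-off would
keep, sink in the ordering and can be truncated away. The two resulting
ordered gene lists are the numerator and denominator signatures of the
balance score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError
from .types import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankRecord:
    """Paired significance ranks of one gene in the IE and ID DEG tables."""

    gene: str
    r_ie: int
    r_id: int

    @property
    def delta_r_ie(self) -> int:
        return self.r_ie - self.r_id

    @property
    def delta_r_id(self) -> int:
        return self.r_id - self.r_ie


@dataclass
class MiracleGeneSets:
    """The derived stimulatory (IE) and suppressive (ID) signature sets.

    Sets produced by :func:`build_miracle_sets` are disjoint by
    construction; hand-built overlapping sets are allowed (the ratio score
    of two identical sets is 1 everywhere) but flagged.
    """

    ie_set: GeneSet
    id_set: GeneSet
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        common = set(self.ie_set.genes) & set(self.id_set.genes)
        if common:
            logger.warning("IE and ID sets overlap on %d genes", len(common))


def exclusive_sets(
    ie_degs: GeneSet, id_degs: GeneSet
) -> tuple[list[str], list[str], list[str]]:
    """Split two DEG lists into IE-only, ID-only and common genes.

    Order within each output follows the input list order. Emits a warning
    when an exclusive list comes out empty (downstream derivation will
    fail without both)."""
    ie = list(ie_degs.genes)
    id_ = list(id_degs.genes)
    id_set = set(id_)
    ie_set = set(ie)
    ie_only = [g for g in ie if g not in id_set]
    id_only = [g for g in id_ if g not in ie_set]
    common = [g for g in ie if g in id_set]
    if not ie_only or not id_only:
        logger.warning(
            "exclusive sets degenerate: %d IE-only, %d ID-only", len(ie_only), len(id_only)
        )
    return ie_only, id_only, common


def delta_r_rank(
    ie_table: pd.DataFrame, id_table: pd.DataFrame, genes: list[str]
) -> list[RankRecord]:
    """Look up each gene's rank in both full DEG tables.

    A gene absent from one table receives rank G+1, one past that table's
    size, keeping the rank difference bounded. Genes absent from both
    tables are excluded with a warning.
    """
    r_ie = ie_table["rank"]
    r_id = id_table["rank"]
    g_ie = len(ie_table)
    g_id = len(id_table)
    records: list[RankRecord] = []
    for gene in genes:
        in_ie = gene in r_ie.index
        in_id = gene in r_id.index
        if not in_ie and not in_id:
            logger.warning("gene %s absent from both DEG tables; excluded", gene)
            continue
        records.append(
            RankRecord(
                gene=gene,
                r_ie=int(r_ie[gene]) if in_ie else g_ie + 1,
                r_id=int(r_id[gene]) if in_id else g_id + 1,
            )
        )
    return records


def build_miracle_sets(
    ie_table: pd.DataFrame,
    id_table: pd.DataFrame,
    ie_only: list[str],
    id_only: list[str],
    top_k: int | str = "all",
) -> MiracleGeneSets:
    """Order the exclusive lists by rank difference and truncate to the top.

    ``ie_set`` contains the IE-only genes sorted ascending by dR_IE (most
    negative, i.e. most IE-specific, first); ``id_set`` symmetrically by
    dR_ID. ``top_k="all"`` keeps the full exclusive lists and uses the rank
    difference only for ordering. Provenance records counts at every stage.
    """
    if not ie_only or not id_only:
        raise ContractError("both exclusive gene lists must be non-empty")
    ie_records = delta_r_rank(ie_table, id_table, ie_only)
    id_records = delta_r_rank(ie_table, id_table, id_only)
    ie_sorted = sorted(ie_records, key=lambda r: (r.delta_r_ie, r.gene))
    id_sorted = sorted(id_records, key=lambda r: (r.delta_r_id, r.gene))

    if top_k == "all":
        k_ie, k_id = len(ie_sorted), len(id_sorted)
    else:
        k = int(top_k)
        if k <= 0:
            raise ContractError("top_k must be positive or 'all'")
        if k > len(ie_sorted) or k > len(id_sorted):
            logger.info(
                "top_k=%d exceeds an exclusive list (%d IE / %d ID); using full lists",
                k, len(ie_sorted), len(id_sorted),
            )
        k_ie, k_id = min(k, len(ie_sorted)), min(k, len(id_sorted))

    ie_set = GeneSet("MIRACLE_IE", tuple(r.gene for r in ie_sorted[:k_ie]))
    id_set = GeneSet("MIRACLE_ID", tuple(r.gene for r in id_sorted[:k_id]))
    provenance = {
        "n_ie_degs": int(len(ie_table)),
        "n_id_degs": int(len(id_table)),
        "n_ie_only": len(ie_only),
        "n_id_only": len(id_only),
        "top_k": top_k,
        "n_ie_set": len(ie_set),
        "n_id_set": len(id_set),
        "rank_records": {
            "ie": [(r.gene, r.r_ie, r.r_id, r.delta_r_ie) for r in ie_sorted],
            "id": [(r.gene, r.r_ie, r.r_id, r.delta_r_id) for r in id_sorted],
        },
    }
    return MiracleGeneSets(ie_set=ie_set, id_set=id_set, provenance=provenance)
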