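"""End-to-end signature discovery: from expression + survival to the score.

Chains the stages: ICR enrichment -> cohort stratification (IE/ID/neutral)
-> pooled tertile differential expression within the IE and within the ID
group -> exclusivity + rank-difference derivation of the two signature
sets -> per-sample balance scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .derivation import MiracleGeneSets, build_miracle_sets, exclusive_sets
from .dge import DEGThresholds, filter_degs, tertile_groups, wilcoxon_de
from .enrichment import nes_series
from .errors import StratificationError
from .scoring import miracle_score
from .survival import CohortStratification, stratify_cohorts
from .synthetic import ICR_SET
from .types import ClinicalTable, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    """All intermediate and final artefacts of one discovery run."""

    icr_nes: pd.Series
    stratification: CohortStratification
    ie_table: pd.DataFrame
    id_table: pd.DataFrame
    ie_degs: GeneSet
    id_degs: GeneSet
    sets: MiracleGeneSets
    scores: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _pooled_de(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    icr_nes: pd.Series,
    cohorts: list[str],
    per_cohort_tertiles: bool,
    log_scale: bool,
) -> pd.DataFrame:
    """Tertile DE pooling all samples of the given cohorts.

    Tertiles are taken on the pooled group's NES distribution by default;
    ``per_cohort_tertiles`` computes them within each cohort first and
    pools the resulting groups.
    """
    samples = clinical.data.loc[clinical.data["cohort"].isin(cohorts), "sample_id"].tolist()
    if per_cohort_tertiles:
        low_ids: list[str] = []
        high_ids: list[str] = []
        for cohort in cohorts:
            ids = clinical.data.loc[clinical.data["cohort"] == cohort, "sample_id"].tolist()
            lo, hi = tertile_groups(icr_nes.loc[ids])
            low_ids += lo
            high_ids += hi
    else:
        low_ids, high_ids = tertile_groups(icr_nes.loc[samples])
    return wilcoxon_de(expr, low_ids, high_ids, log_scale=log_scale)


def run_discovery(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    icr_set: GeneSet = ICR_SET,
    thresholds: DEGThresholds = DEGThresholds(),
    top_k: int | str = "all",
    p_threshold: float = 0.1,
    min_events: int = 5,
    per_cohort_tertiles: bool = False,
    log_scale: bool = False,
    min_overlap: float = 0.5,
) -> DiscoveryResult:
    """Derive the signature sets and score every sample.

    Raises :class:`StratificationError` when no cohort lands in the IE or
    in the ID class (both groups are required to derive the signatures).
    """
    icr_nes = nes_series(expr, icr_set)
    strat = stratify_cohorts(clinical, icr_nes, p_threshold=p_threshold, min_events=min_events)
    ie_cohorts = strat.cohorts_in_class("IE")
    id_cohorts = strat.cohorts_in_class("ID")
    logger.info("stratification: IE=%s ID=%s neutral=%s", ie_cohorts, id_cohorts,
                strat.cohorts_in_class("neutral"))
    if not ie_cohorts or not id_cohorts:
        raise StratificationError(
            f"need at least one IE and one ID cohort; got IE={ie_cohorts}, ID={id_cohorts}"
        )

    ie_table = _pooled_de(expr, clinical, icr_nes, ie_cohorts, per_cohort_tertiles, log_scale)
    id_table = _pooled_de(expr, clinical, icr_nes, id_cohorts, per_cohort_tertiles, log_scale)
    ie_degs = filter_degs(ie_table, thresholds, name="IE_DEGs")
    id_degs = filter_degs(id_table, thresholds, name="ID_DEGs")
    if ie_degs is None or id_degs is None:
        raise StratificationError("a DEG list is empty; cannot derive signature sets")

    ie_only, id_only, common = exclusive_sets(ie_degs, id_degs)
    sets = build_miracle_sets(ie_table, id_table, ie_only, id_only, top_k=top_k)
    sets.provenance["n_common"] = len(common)
    sets.provenance["n_ie_degs_filtered"] = len(ie_degs)
    sets.provenance["n_id_degs_filtered"] = len(id_degs)
    scores = miracle_score(expr, sets, min_overlap=min_overlap)

    return DiscoveryResult(
        icr_nes=icr_nes,
        stratification=strat,
        ie_table=ie_table,
        id_table=id_table,
        ie_degs=ie_degs,
        id_degs=id_degs,
        sets=sets,
        scores=scores,
        provenance={
            "ie_cohorts": ie_cohorts,
            "id_cohorts": id_cohorts,
            "neutral_cohorts": strat.cohorts_in_class("neutral"),
            "excluded_cohorts": strat.excluded,
            **{k: v for k, v in sets.provenance.items() if k != "rank_records"},
        },
    )
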