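"""Per-sample balance score: ratio of IE-set to ID-set enrichment.

For each sample the score is NES(IE set) / NES(ID set), both computed by
the rank-based single-sample gene-set test. Because each NES depends only
on the ranking of genes within that one sample, the score is identical
whether a sample is scored alone or inside any matrix, and is invariant to
positive scaling or any strictly increasing transform of the profile — no
dataset-level normalisation is needed, so the score can be applied patient
by patient.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .derivation import MiracleGeneSets
from .enrichment import score_matrix
from .errors import NoOverlapError
from .types import ExpressionMatrix

logger = logging.getLogger(__name__)


def _check_overlap(expr: ExpressionMatrix, sets: MiracleGeneSets, min_overlap: float) -> None:
    genes = set(expr.gene_ids)
    for gs in (sets.ie_set, sets.id_set):
        present = [g for g in gs.genes if g in genes]
        if not present:
            raise NoOverlapError(f"gene set {gs.name!r} shares no genes with the matrix")
        frac = len(present) / len(gs)
        if frac < min_overlap:
            missing = sorted(set(gs.genes) - genes)
            logger.warning(
                "gene set %s: only %.0f%% of genes present (missing e.g. %s)",
                gs.name, 100 * frac, missing[:10],
            )


def miracle_score(
    expr: ExpressionMatrix,
    sets: MiracleGeneSets,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Score every sample of a matrix.

    Returns a frame indexed by sample with columns ``nes_ie``, ``nes_id``,
    ``score`` (= nes_ie / nes_id), ``log2_score`` (a derived convenience
    column for symmetric survival modelling) and ``error``. A sample with
    NES(ID) = 0 gets an error record (score NaN); other samples are
    unaffected.
    """
    _check_overlap(expr, sets, min_overlap)
    tidy = score_matrix(expr, [sets.ie_set, sets.id_set])
    wide = tidy.pivot(index="sample_id", columns="set_name", values="nes")
    wide = wide.reindex(expr.sample_ids)
    nes_ie = wide[sets.ie_set.name].to_numpy()
    nes_id = wide[sets.id_set.name].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(nes_id > 0, nes_ie / nes_id, np.nan)
        log2_score = np.where(score > 0, np.log2(np.where(score > 0, score, 1.0)), np.nan)
    errors = [
        "NES of the ID set is zero; ratio undefined" if nid == 0 else None for nid in nes_id
    ]
    n_bad = sum(e is not None for e in errors)
    if n_bad:
        logger.warning("%d sample(s) have NES(ID)=0; score undefined for them", n_bad)
    return pd.DataFrame(
        {
            "nes_ie": nes_ie,
            "nes_id": nes_id,
            "score": score,
            "log2_score": log2_score,
            "error": errors,
        },
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )


def single_sample_score(profile: pd.Series, sets: MiracleGeneSets, min_overlap: float = 0.5) -> pd.Series:
    """Score one expression profile in isolation.

    Guaranteed identical to the corresponding row of :func:`miracle_score`
    on any matrix containing the sample — the incremental, patient-by-
    patient application the ratio score is designed for.
    """
    name = str(profile.name) if profile.name is not None else "sample"
    expr = ExpressionMatrix(list(profile.index), [name], profile.to_numpy()[:, None])
    return miracle_score(expr, sets, min_overlap=min_overlap).iloc[0]
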