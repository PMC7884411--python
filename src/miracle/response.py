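"""Checkpoint-inhibitor response labelling and ROC evaluation.

RECIST categories map deterministically to a binary responder label:
progressive disease (PD) is a non-responder; complete response, partial
response and stable disease (CR/PR/SD) are responders. The score's
discrimination is summarised by the ROC AUC, equal to the probability that
a random responder scores above a random non-responder (ties counting one
half), plus a Welch two-sample t comparison of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from sklearn.metrics import roc_curve

from .errors import DegenerateDataError, LabellingError

RECIST_CODES = ("CR", "PR", "SD", "PD")

_SYNONYMS = {
    "CR": "CR", "COMPLETE RESPONSE": "CR",
    "PR": "PR", "PARTIAL RESPONSE": "PR",
    "SD": "SD", "STABLE DISEASE": "SD",
    "PD": "PD", "PROGRESSIVE DISEASE": "PD",
}

TIMEPOINTS = ("pre-treatment", "on-treatment", "unknown")


def label_responders(recist: pd.Series, timepoint: pd.Series | None = None) -> pd.DataFrame:
    """Map RECIST codes to binary responder labels.

    PD -> 0 (non-responder); CR, PR, SD -> 1 (responder). Long and short
    code forms are accepted, case-insensitively.

    Returns a frame indexed by sample with columns ``recist``, ``responder``
    and ``timepoint``.
    """
    codes = []
    for sample, raw in recist.items():
        key = str(raw).strip().upper()
        if key not in _SYNONYMS:
            raise LabellingError(f"sample {sample}: unknown RECIST code {raw!r}")
        codes.append(_SYNONYMS[key])
    tp = (
        timepoint.reindex(recist.index).fillna("unknown")
        if timepoint is not None
        else pd.Series("unknown", index=recist.index)
    )
    bad_tp = set(tp) - set(TIMEPOINTS)
    if bad_tp:
        raise LabellingError(f"unknown timepoint labels: {sorted(bad_tp)}")
    return pd.DataFrame(
        {
            "recist": codes,
            "responder": [0 if c == "PD" else 1 for c in codes],
            "timepoint": tp.to_numpy(),
        },
        index=pd.Index(recist.index.astype(str), name="sample_id"),
    )


@dataclass(frozen=True)
class RocResult:
    """AUC with the ROC curve points at every distinct score threshold."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(scores: pd.Series, labels: pd.DataFrame) -> RocResult:
    """ROC AUC of a score for the responder label.

    AUC is computed from midranks (the Mann-Whitney form of pairwise
    concordance, ties contributing one half), which equals the area under
    the trapezoidal ROC curve.
    """
    y = labels["responder"].reindex(scores.index).to_numpy()
    if np.isnan(y.astype(float)).any():
        raise LabellingError("scores contain samples without a response label")
    x = scores.to_numpy(dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC undefined: only one response class present")
    ranks = rankdata(x)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y, x)
    return RocResult(float(auc), fpr, tpr, thresholds, n_pos, n_neg)


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample t-test of responder vs non-responder scores."""

    t: float
    p: float
    df: float
    mean_responders: float
    mean_non_responders: float
    n_responders: int
    n_non_responders: int


def group_compare(scores: pd.Series, labels: pd.DataFrame) -> GroupComparison:
    """Welch t comparison of scores between responders and non-responders."""
    y = labels["responder"].reindex(scores.index).to_numpy()
    x = scores.to_numpy(dtype=float)
    resp = x[y == 1]
    non = x[y == 0]
    if resp.size < 2 or non.size < 2:
        raise DegenerateDataError("both groups need >= 2 samples")
    if resp.std(ddof=1) == 0 and non.std(ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance; t undefined")
    res = ttest_ind(resp, non, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    v1, v0 = resp.var(ddof=1) / resp.size, non.var(ddof=1) / non.size
    df = (v1 + v0) ** 2 / (v1**2 / (resp.size - 1) + v0**2 / (non.size - 1))
    return GroupComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(df),
        mean_responders=float(resp.mean()),
        mean_non_responders=float(non.mean()),
        n_responders=int(resp.size),
        n_non_responders=int(non.size),
    )
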