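"""Elastic-net association between somatic mutations and the balance score.

A penalised linear model predicts each sample's score (log2 by default,
for symmetry of the ratio) from its binary mutation profile, with the
cohort entering as an unpenalised covariate. Cohort effects are profiled
out exactly by centring the response and every mutation column within
cohort (for a penalty that does not touch the cohort coefficients this is
equivalent to fitting unpenalised cohort dummies). Genes with negative
coefficients are reported as score-decreasing, positive as
score-increasing; predictive accuracy is the tenfold cross-validated
Spearman correlation between predicted and observed scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import ContractError, DegenerateDataError
from .types import MutationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElasticNetConfig:
    """Hyperparameters of the mutation-association model.

    l1_ratio : L1/L2 mixing (0.5 = equal-weight elastic net).
    alpha : fixed penalty strength; ``None`` selects it on a grid by inner
        cross-validation. ``0`` gives the unpenalised least-squares solution.
    n_alphas : size of the automatic penalty grid.
    cv_folds : outer folds for the reported Spearman accuracy.
    inner_folds : folds of the penalty-selection cross-validation.
    use_log2 : model log2(score) rather than the raw ratio.
    """

    l1_ratio: float = 0.5
    alpha: float | None = None
    n_alphas: int = 30
    cv_folds: int = 10
    inner_folds: int = 5
    use_log2: bool = True
    seed: int = 0


@dataclass
class AssociationModel:
    """Fitted coefficients plus cross-validated accuracy."""

    coefficients: pd.Series
    cv_correlation: float
    cv_correlation_sd: float
    fold_correlations: list[float]
    alpha: float
    l1_ratio: float
    cohorts: list[str] = field(default_factory=list)

    @property
    def decrease_genes(self) -> list[str]:
        return self.coefficients[self.coefficients < 0].index.tolist()

    @property
    def increase_genes(self) -> list[str]:
        return self.coefficients[self.coefficients > 0].index.tolist()


def _center_within_cohort(X: np.ndarray, y: np.ndarray, cohorts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc = X.astype(float).copy()
    yc = y.astype(float).copy()
    for c in np.unique(cohorts):
        mask = cohorts == c
        Xc[mask] -= Xc[mask].mean(axis=0)
        yc[mask] -= yc[mask].mean()
    return Xc, yc


def _fit(X: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float, seed: int) -> np.ndarray:
    if alpha == 0:
        coef, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
        return coef
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model.coef_


def fit_elastic_net(
    mut: MutationMatrix,
    scores: pd.Series,
    cohorts: pd.Series | None = None,
    config: ElasticNetConfig = ElasticNetConfig(),
) -> AssociationModel:
    """Fit the mutation -> score elastic net and cross-validate it.

    Parameters
    ----------
    mut : binary gene-by-sample mutation matrix.
    scores : per-sample balance scores, indexed by sample id.
    cohorts : optional per-sample cohort labels (unpenalised covariate).
    """
    samples = mut.sample_ids
    y = scores.reindex(samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ContractError("scores missing for some mutation-matrix samples")
    if config.use_log2:
        if (y <= 0).any():
            raise ContractError("log2 response requires strictly positive scores")
        y = np.log2(y)
    if np.unique(y).size == 1:
        raise DegenerateDataError("score vector is constant; association undefined")
    X = mut.values.T.astype(float)  # samples x genes

    if cohorts is not None:
        coh = cohorts.reindex(samples).astype(str).to_numpy()
        if pd.isna(cohorts.reindex(samples)).any():
            raise ContractError("cohort labels missing for some samples")
        cohort_levels = sorted(set(coh))
        X_fit, y_fit = _center_within_cohort(X, y, coh)
    else:
        coh = None
        cohort_levels = []
        X_fit, y_fit = X - X.mean(axis=0), y - y.mean()

    zero_cols = np.flatnonzero(mut.values.sum(axis=1) == 0)
    if zero_cols.size:
        logger.info("%d mutation columns are all-zero; coefficients forced to 0", zero_cols.size)

    rng_seed = config.seed
    if config.alpha is None:
        cv_model = ElasticNetCV(
            l1_ratio=config.l1_ratio,
            alphas=config.n_alphas,  # size of the automatic penalty grid
            cv=KFold(config.inner_folds, shuffle=True, random_state=rng_seed),
            max_iter=50_000,
            random_state=rng_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_model.fit(X_fit, y_fit)
        alpha = float(cv_model.alpha_)
        coef = cv_model.coef_
    else:
        alpha = float(config.alpha)
        coef = _fit(X_fit, y_fit, alpha, config.l1_ratio, rng_seed)
    coef = np.asarray(coef, dtype=float)
    coef[zero_cols] = 0.0

    # outer cross-validation: refit at the selected penalty on each training
    # split, Spearman on the held-out samples
    folds = KFold(config.cv_folds, shuffle=True, random_state=rng_seed)
    fold_cors: list[float] = []
    for train, test in folds.split(X_fit):
        c = _fit(X_fit[train], y_fit[train], alpha, config.l1_ratio, rng_seed)
        pred = X_fit[test] @ c
        if np.unique(pred).size == 1 or np.unique(y_fit[test]).size == 1:
            fold_cors.append(0.0)  # constant prediction carries no ranking information
            continue
        rho = spearmanr(pred, y_fit[test]).statistic
        fold_cors.append(float(rho))
    return AssociationModel(
        coefficients=pd.Series(coef, index=mut.gene_ids, name="coefficient"),
        cv_correlation=float(np.mean(fold_cors)),
        cv_correlation_sd=float(np.std(fold_cors, ddof=1)) if len(fold_cors) > 1 else 0.0,
        fold_correlations=fold_cors,
        alpha=alpha,
        l1_ratio=config.l1_ratio,
        cohorts=cohort_levels,
    )
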