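"""Cox proportional-hazards fitting, cohort stratification and model comparison.

Cohorts are classified by the sign and significance of the association
between the continuous ICR enrichment score and overall survival: immune
"enabled" (IE) when a higher score is protective (HR < 1, p < 0.1), immune
"disabled" (ID) when it is deleterious (HR > 1, p < 0.1), neutral otherwise.
Pan-cancer models stack cohorts with a cohort factor:

    Model 1: Surv ~ predictor + cohort
    Model 2: Surv ~ predictor + cohort + age + gender + stage
    Model 3: Surv ~ cohort + age + gender + stage

Nested models are compared with a likelihood-ratio chi-square test. Ties in
event times are handled with the Efron approximation throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from scipy.stats import chi2

from .errors import (
    ContractError,
    ConvergenceError,
    DegenerateDataError,
    NonIdentifiableError,
    StratificationError,
    ValidationError,
)
from .types import ClinicalTable

logger = logging.getLogger(__name__)

#: Sub-stage harmonisation applied before ordinal encoding (IA -> I, ...).
STAGE_MAP = {
    "IA": "I", "IB": "I", "IC": "I",
    "IIA": "II", "IIB": "II", "IIC": "II",
    "IIIA": "III", "IIIB": "III", "IIIC": "III",
    "IVA": "IV", "IVB": "IV", "IVC": "IV",
}
STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass(frozen=True)
class SurvivalFit:
    """Wald summary of one predictor in a fitted Cox model."""

    predictor_name: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    loglik: float
    n: int
    n_events: int


@dataclass(frozen=True)
class SurvivalModelSpec:
    """A named Cox model formula: optional predictor plus covariate terms."""

    name: str
    predictor: str | None
    covariates: tuple[str, ...] = ()

    @property
    def terms(self) -> tuple[str, ...]:
        pred = (self.predictor,) if self.predictor else ()
        return pred + self.covariates


def model_specs(predictor: str = "score") -> dict[str, SurvivalModelSpec]:
    """The three standard pan-cancer model formulas."""
    return {
        "Model1": SurvivalModelSpec("Model1", predictor, ("cohort",)),
        "Model2": SurvivalModelSpec("Model2", predictor, ("cohort", "age", "gender", "stage")),
        "Model3": SurvivalModelSpec("Model3", None, ("cohort", "age", "gender", "stage")),
    }


@dataclass
class CohortStratification:
    """IE/ID/neutral class per cohort with the underlying univariate fits."""

    classes: dict[str, str]
    fits: dict[str, SurvivalFit]
    excluded: dict[str, str] = field(default_factory=dict)

    def cohorts_in_class(self, label: str) -> list[str]:
        return sorted(c for c, k in self.classes.items() if k == label)


def _encode_stage(values: pd.Series) -> pd.Series:
    cleaned = values.astype(str).str.strip().str.upper().str.replace("STAGE ", "", regex=False)
    cleaned = cleaned.replace(STAGE_MAP)
    out = cleaned.map(STAGE_ORDER)
    return out


def _design_frame(
    clinical: ClinicalTable,
    predictor: pd.Series | None,
    covariates: tuple[str, ...],
    predictor_name: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the lifelines design frame on complete cases.

    Categorical covariates (cohort, gender) are dummy-coded against the
    first level; stage is mapped to an ordinal 1..4. Rows missing any
    requested term are dropped and counted.
    """
    df = clinical.data.set_index("sample_id")
    out = pd.DataFrame(index=df.index)
    out["time"] = df["time"]
    out["event"] = df["event"]
    columns: list[str] = []
    if predictor is not None:
        aligned = predictor.reindex(df.index)
        out[predictor_name] = pd.to_numeric(aligned, errors="coerce")
        columns.append(predictor_name)
    for cov in covariates:
        if cov not in df.columns:
            raise ContractError(f"covariate {cov!r} not present in clinical table")
        if cov in ("cohort", "gender"):
            cats = df[cov].astype("category")
            dummies = pd.get_dummies(cats, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                out[c] = dummies[c]
                columns.append(c)
        elif cov == "stage":
            out["stage"] = _encode_stage(df[cov])
            columns.append("stage")
        else:
            out[cov] = pd.to_numeric(df[cov], errors="coerce")
            columns.append(cov)
    n_before = len(out)
    out = out.dropna()
    dropped = n_before - len(out)
    if dropped:
        logger.info("complete-case filtering dropped %d of %d rows", dropped, n_before)
    return out, columns


def _fit_cox(design: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except _LLConvergenceError as exc:
        raise ConvergenceError(f"Cox partial likelihood did not converge: {exc}") from exc
    return cph


def cox_fit(
    clinical: ClinicalTable,
    predictor: pd.Series,
    covariates: tuple[str, ...] = (),
    predictor_name: str = "predictor",
) -> SurvivalFit:
    """Fit ``Surv(time, event) ~ predictor (+ covariates)`` by Cox regression.

    Efron tie handling; Wald statistics for the predictor; 95% CI on the
    hazard ratio.

    Raises
    ------
    DegenerateDataError
        Fewer than two events after complete-case filtering.
    NonIdentifiableError
        Predictor constant across the analysed samples.
    ConvergenceError
        Monotone partial likelihood / non-convergence, with diagnostic text.
    """
    design, _ = _design_frame(clinical, predictor, covariates, predictor_name)
    if design["event"].sum() < 2:
        raise DegenerateDataError(f"only {int(design['event'].sum())} events; need >= 2")
    if design[predictor_name].nunique() < 2:
        raise NonIdentifiableError("predictor is constant across samples")
    cph = _fit_cox(design)
    summary = cph.summary.loc[predictor_name]
    return SurvivalFit(
        predictor_name=predictor_name,
        beta=float(summary["coef"]),
        hr=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        p=float(summary["p"]),
        loglik=float(cph.log_likelihood_),
        n=int(len(design)),
        n_events=int(design["event"].sum()),
    )


def stratify_cohorts(
    clinical: ClinicalTable,
    nes: pd.Series,
    p_threshold: float = 0.1,
    min_events: int = 5,
) -> CohortStratification:
    """Classify each cohort as IE, ID or neutral from the ICR-survival fit.

    Per cohort, a univariate Cox model on the continuous NES is fitted;
    IE if HR < 1 and p < ``p_threshold``, ID if HR > 1 and p < threshold,
    neutral otherwise. Cohorts with fewer than ``min_events`` events are
    excluded (too few deaths for survival estimation) and reported.
    """
    classes: dict[str, str] = {}
    fits: dict[str, SurvivalFit] = {}
    excluded: dict[str, str] = {}
    cohorts = clinical.cohorts
    if len(cohorts) < 2:
        raise StratificationError("need at least two cohorts to stratify")
    for cohort in cohorts:
        sub = ClinicalTable(clinical.data[clinical.data["cohort"] == cohort])
        n_events = int(sub.data["event"].sum())
        if n_events < min_events:
            excluded[cohort] = f"{n_events} events < minimum {min_events}"
            logger.info("cohort %s excluded from stratification: %s", cohort, excluded[cohort])
            continue
        try:
            fit = cox_fit(sub, nes, predictor_name="icr_nes")
        except (DegenerateDataError, NonIdentifiableError, ConvergenceError) as exc:
            excluded[cohort] = str(exc)
            continue
        fits[cohort] = fit
        if fit.hr < 1 and fit.p < p_threshold:
            classes[cohort] = "IE"
        elif fit.hr > 1 and fit.p < p_threshold:
            classes[cohort] = "ID"
        else:
            classes[cohort] = "neutral"
    if not classes:
        raise StratificationError("no cohort eligible for stratification")
    return CohortStratification(classes=classes, fits=fits, excluded=excluded)


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test between two nested Cox models."""

    larger: str
    smaller: str
    chi2: float
    df: int
    p: float
    loglik_larger: float
    loglik_smaller: float
    n: int


def compare_models(
    clinical: ClinicalTable,
    predictor: pd.Series,
    larger: SurvivalModelSpec,
    smaller: SurvivalModelSpec,
    predictor_name: str = "score",
) -> ModelComparison:
    """Likelihood-ratio chi-square between two nested model specs.

    Both models are fitted on the complete cases of the *larger* model so
    the partial likelihoods are comparable. ``df`` is the difference in the
    number of estimated coefficients.
    """
    if not set(smaller.terms) <= set(larger.terms):
        raise ContractError(f"{smaller.name} is not nested in {larger.name}")
    design_large, cols_large = _design_frame(
        clinical, predictor if larger.predictor else None, larger.covariates, predictor_name
    )
    # restrict the smaller model to the larger model's complete cases
    restricted = ClinicalTable(clinical.data[clinical.data["sample_id"].isin(design_large.index)])
    design_small, cols_small = _design_frame(
        restricted, predictor if smaller.predictor else None, smaller.covariates, predictor_name
    )
    if design_large["event"].sum() < 2:
        raise DegenerateDataError("fewer than two events on complete cases")
    ll_large = float(_fit_cox(design_large).log_likelihood_) if cols_large else 0.0
    ll_small = float(_fit_cox(design_small).log_likelihood_) if cols_small else 0.0
    df = len(cols_large) - len(cols_small)
    stat = max(0.0, 2.0 * (ll_large - ll_small))
    if df == 0:
        p = 1.0
        stat = 0.0
    else:
        p = float(chi2.sf(stat, df))
    return ModelComparison(
        larger=larger.name,
        smaller=smaller.name,
        chi2=stat,
        df=df,
        p=p,
        loglik_larger=ll_large,
        loglik_smaller=ll_small,
        n=int(len(design_large)),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Returns adjusted p-values aligned with the input order; output is
    elementwise >= the input and <= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * p.size / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out
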