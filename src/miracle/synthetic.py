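"""Synthetic multi-cohort data with the structure the balance score assumes.

Each sample carries two latent programme activities: stimulation ``A``
(Th1-polarised immune activation) and suppression ``S`` (TGF-beta/stromal
style counter-regulation). Cohort archetypes differ in which latent
dominates: in IE-like ("immune enabled") cohorts ``A`` has large variance
and drives the infiltration signal, so infiltration is protective; in
ID-like cohorts ``S`` dominates, so an infiltrated-looking tumour is
actually suppressed and infiltration predicts worse outcome. A small
positive corr(A, S) in every cohort mimics compensatory immune resistance
— suppressive signals rising alongside stimulation.

Expression is lognormal: log2 values are a per-gene baseline plus a
programme shift plus Gaussian noise. ICR-like genes (named after the
20-gene Th1 signature) shift with ``A + kappa*S`` — infiltration with a
suppressive admixture; planted IE-programme genes shift with ``A`` alone,
ID-programme genes with ``S`` alone; the remaining genes are noise.
Survival is exponential with hazard proportional to ``exp(-gamma*(A - S))``
(the true balance is protective), under independent uniform censoring.
Mutations are sparse Bernoulli indicators; planted driver genes shift
``A`` additively for carriers, and expression/survival are regenerated
consistently. Responder status is Bernoulli with a logistic probability in
the true balance, then spread over RECIST bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .response import label_responders
from .types import ClinicalTable, ExpressionMatrix, GeneSet, MutationMatrix

#: The 20-gene Th1/cytotoxicity "immunologic constant of rejection" signature
#: used to name the planted infiltration genes, so the synthetic data can be
#: scored with the real signature out of the box.
ICR_GENES = (
    "IFNG", "TBX21", "CD8A", "CD8B", "IL12B", "STAT1", "IRF1",
    "CXCL9", "CXCL10", "CCL5",
    "GNLY", "PRF1", "GZMA", "GZMB", "GZMH",
    "CD274", "PDCD1", "CTLA4", "FOXP3", "IDO1",
)

ICR_SET = GeneSet("ICR", ICR_GENES)


@dataclass(frozen=True)
class CohortArchetype:
    """Latent-programme distribution of one cohort type.

    ``sd_a``/``sd_s`` are the standard deviations of the stimulation and
    suppression latents; ``corr_as`` their correlation. IE-like cohorts are
    stimulation-dominated, ID-like cohorts suppression-dominated.
    """

    sd_a: float
    sd_s: float
    corr_as: float


ARCHETYPES = {
    "IE": CohortArchetype(sd_a=1.0, sd_s=0.3, corr_as=0.1),
    "ID": CohortArchetype(sd_a=0.3, sd_s=1.0, corr_as=0.1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults are the package's reference scenario.

    Counts: 3 cohorts of 200 samples, 2000 genes of which 20 ICR-like,
    50 IE-programme and 50 ID-programme. Effects are in units of the
    log2-scale noise SD. ``kappa`` is the suppressive admixture of the
    infiltration signal; ``gamma`` couples the hazard to the true balance
    A - S. The mutation panel has 200 genes with five score-decreasing and
    five score-increasing planted drivers.
    """

    n_cohorts: int = 3
    samples_per_cohort: int = 200
    n_genes: int = 2000
    n_icr_genes: int = 20
    n_ie_genes: int = 50
    n_id_genes: int = 50
    archetypes: tuple[str, ...] = ("IE", "IE", "ID")
    icr_effect: float = 1.5
    programme_effect: float = 2.0
    kappa: float = 0.8
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    gamma: float = 0.8
    base_hazard: float = 8e-4  # per day; mean survival 1250 days at balance 0
    censoring: float = 0.35  # target censored fraction
    mutation_panel: int = 200
    n_negative_drivers: int = 5
    n_positive_drivers: int = 5
    mutation_rate: float = 0.08
    mutation_effect: float = 1.0  # latent shift (SD units) per carried driver
    response_slope: float = 1.5
    response_intercept: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        counts = (
            self.n_cohorts, self.samples_per_cohort, self.n_genes,
            self.n_icr_genes, self.n_ie_genes, self.n_id_genes,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all simulation counts must be positive")
        if self.n_icr_genes + self.n_ie_genes + self.n_id_genes > self.n_genes:
            raise ValidationError("planted gene counts exceed n_genes")
        if self.n_icr_genes > len(ICR_GENES):
            raise ValidationError(f"at most {len(ICR_GENES)} ICR-like genes supported")
        if not 0 <= self.censoring < 1:
            raise ValidationError("censoring rate must be in [0, 1)")
        if len(self.archetypes) != self.n_cohorts:
            raise ValidationError("need one archetype per cohort")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes: {sorted(unknown)}")
        if self.n_negative_drivers + self.n_positive_drivers > self.mutation_panel:
            raise ValidationError("planted drivers exceed the mutation panel size")


@dataclass
class SimulationTruth:
    """Everything planted: latents, memberships and raw random draws.

    Storing the noise matrix and the survival/censoring uniforms makes the
    observed data a deterministic function of the latents, so mutation
    effects can be propagated by regeneration.
    """

    config: SimulationConfig
    sample_ids: list[str]
    gene_ids: list[str]
    cohort_of: np.ndarray  # cohort label per sample
    archetype_of: dict[str, str]  # cohort -> archetype
    a: np.ndarray
    s: np.ndarray
    icr_genes: list[str]
    ie_genes: list[str]
    id_genes: list[str]
    baselines: np.ndarray = field(repr=False)
    noise: np.ndarray = field(repr=False)
    u_survival: np.ndarray = field(repr=False)
    censor_times: np.ndarray = field(repr=False)
    covariates: pd.DataFrame = field(repr=False)

    @property
    def balance(self) -> np.ndarray:
        """The planted stimulation-suppression balance A - S."""
        return self.a - self.s


@dataclass
class SimulatedCohorts:
    """Generated dataset bundle: observables plus the ground truth."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: SimulationTruth


def _expression_from_latents(truth: SimulationTruth) -> ExpressionMatrix:
    cfg = truth.config
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    shifts = np.zeros((len(truth.gene_ids), len(truth.sample_ids)))
    icr_signal = cfg.icr_effect * cfg.noise_sd * (truth.a + cfg.kappa * truth.s)
    ie_signal = cfg.programme_effect * cfg.noise_sd * truth.a
    id_signal = cfg.programme_effect * cfg.noise_sd * truth.s
    for g in truth.icr_genes:
        shifts[gene_index[g]] = icr_signal
    for g in truth.ie_genes:
        shifts[gene_index[g]] = ie_signal
    for g in truth.id_genes:
        shifts[gene_index[g]] = id_signal
    log2_expr = truth.baselines[:, None] + shifts + truth.noise
    return ExpressionMatrix(list(truth.gene_ids), list(truth.sample_ids), np.exp2(log2_expr))


def _clinical_from_latents(truth: SimulationTruth) -> ClinicalTable:
    cfg = truth.config
    hazard = cfg.base_hazard * np.exp(-cfg.gamma * truth.balance)
    t_event = -np.log(truth.u_survival) / hazard
    time = np.minimum(t_event, truth.censor_times)
    event = (t_event <= truth.censor_times).astype(int)
    df = pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "cohort": truth.cohort_of,
            "time": np.round(time, 1),
            "event": event,
        }
    )
    return ClinicalTable(pd.concat([df, truth.covariates.reset_index(drop=True)], axis=1))


def _censor_horizon(cfg: SimulationConfig) -> float:
    """Uniform-censoring horizon hitting the target censored fraction.

    For T ~ Exp(lambda0) and C ~ U(0, B), P(censored) = (1 - e^-x)/x with
    x = lambda0*B; solve for x by bisection at the baseline hazard.
    """
    r = cfg.censoring
    if r == 0:
        return np.inf
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = (lo + hi) / 2
        frac = (1 - np.exp(-mid)) / mid
        if frac > r:
            lo = mid
        else:
            hi = mid
    return lo / cfg.base_hazard


def simulate_cohorts(config: SimulationConfig = SimulationConfig()) -> SimulatedCohorts:
    """Draw one multi-cohort dataset from the generative model.

    Deterministic for a fixed config (including its seed): reruns are
    bit-identical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cohorts * cfg.samples_per_cohort

    cohort_labels = [f"C{i + 1}" for i in range(cfg.n_cohorts)]
    archetype_of = dict(zip(cohort_labels, cfg.archetypes))
    cohort_of = np.repeat(cohort_labels, cfg.samples_per_cohort)
    sample_ids = [
        f"{c}S{j + 1:03d}" for c in cohort_labels for j in range(cfg.samples_per_cohort)
    ]

    a = np.empty(n)
    s = np.empty(n)
    for c in cohort_labels:
        arch = ARCHETYPES[archetype_of[c]]
        mask = cohort_of == c
        cov = np.array(
            [
                [arch.sd_a**2, arch.corr_as * arch.sd_a * arch.sd_s],
                [arch.corr_as * arch.sd_a * arch.sd_s, arch.sd_s**2],
            ]
        )
        latents = rng.multivariate_normal([0.0, 0.0], cov, size=int(mask.sum()))
        a[mask] = latents[:, 0]
        s[mask] = latents[:, 1]

    icr_genes = list(ICR_GENES[: cfg.n_icr_genes])
    ie_genes = [f"IEP{i + 1:04d}" for i in range(cfg.n_ie_genes)]
    id_genes = [f"IDP{i + 1:04d}" for i in range(cfg.n_id_genes)]
    n_noise = cfg.n_genes - len(icr_genes) - len(ie_genes) - len(id_genes)
    noise_genes = [f"GENE{i + 1:05d}" for i in range(n_noise)]
    gene_ids = icr_genes + ie_genes + id_genes + noise_genes

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n))
    u_survival = rng.uniform(size=n)
    horizon = _censor_horizon(cfg)
    censor_times = rng.uniform(0.0, 1.0, size=n) * horizon if np.isfinite(horizon) else np.full(n, np.inf)

    covariates = pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(62, 10, size=n), 20, 95), 1),
            "gender": rng.choice(["F", "M"], size=n),
            "stage": rng.choice(["I", "IIA", "II", "IIIB", "III", "IV"], size=n),
        }
    )

    truth = SimulationTruth(
        config=cfg,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        cohort_of=cohort_of,
        archetype_of=archetype_of,
        a=a,
        s=s,
        icr_genes=icr_genes,
        ie_genes=ie_genes,
        id_genes=id_genes,
        baselines=baselines,
        noise=noise,
        u_survival=u_survival,
        censor_times=censor_times,
        covariates=covariates,
    )
    return SimulatedCohorts(
        expression=_expression_from_latents(truth),
        clinical=_clinical_from_latents(truth),
        truth=truth,
    )


def simulate_mutations(
    config: SimulationConfig, sim: SimulatedCohorts
) -> tuple[MutationMatrix, SimulatedCohorts]:
    """Draw sparse mutations and propagate planted driver effects.

    The first ``n_negative_drivers`` panel genes subtract
    ``mutation_effect`` from a carrier's stimulation latent (decreasing the
    balance), the next ``n_positive_drivers`` add it. Expression and
    survival are regenerated from the shifted latents with the *same* noise
    and uniform draws, so the returned bundle differs from the input only
    through the mutations.
    """
    cfg = config
    truth = sim.truth
    rng = np.random.default_rng(cfg.seed + 104_729)  # independent stream
    n = len(truth.sample_ids)
    gene_ids = [f"MUT{i + 1:04d}" for i in range(cfg.mutation_panel)]
    values = (rng.uniform(size=(cfg.mutation_panel, n)) < cfg.mutation_rate).astype(np.int8)
    mut = MutationMatrix(gene_ids, list(truth.sample_ids), values)

    effects = np.zeros(cfg.mutation_panel)
    effects[: cfg.n_negative_drivers] = -cfg.mutation_effect
    effects[cfg.n_negative_drivers : cfg.n_negative_drivers + cfg.n_positive_drivers] = (
        cfg.mutation_effect
    )
    shift = effects @ values  # per-sample latent shift
    new_truth = replace(truth, a=truth.a + shift)
    updated = SimulatedCohorts(
        expression=_expression_from_latents(new_truth),
        clinical=_clinical_from_latents(new_truth),
        truth=new_truth,
    )
    return mut, updated


def mutation_driver_genes(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Names of the planted (negative, positive) driver genes."""
    neg = [f"MUT{i + 1:04d}" for i in range(config.n_negative_drivers)]
    pos = [
        f"MUT{i + 1:04d}"
        for i in range(
            config.n_negative_drivers, config.n_negative_drivers + config.n_positive_drivers
        )
    ]
    return neg, pos


def simulate_response(truth: SimulationTruth, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Assign RECIST codes with responder probability logistic in the balance.

    Responder status is Bernoulli(sigmoid(slope*(A - S) + intercept));
    non-responders are PD, responders are spread over SD/PR/CR bands.
    Labels come back through the standard RECIST mapping, so they are
    consistent with the response module by construction.
    """
    cfg = config if config is not None else truth.config
    rng = np.random.default_rng(cfg.seed + 15_485_863)
    p = 1.0 / (1.0 + np.exp(-(cfg.response_slope * truth.balance + cfg.response_intercept)))
    responder = rng.uniform(size=p.size) < p
    band = rng.uniform(size=p.size)
    codes = np.where(
        ~responder, "PD", np.where(band < 0.5, "SD", np.where(band < 0.8, "PR", "CR"))
    )
    recist = pd.Series(codes, index=pd.Index(truth.sample_ids, name="sample_id"))
    return label_responders(recist)
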