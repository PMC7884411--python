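"""Cox fitting against an Efron partial-likelihood oracle, stratification,
nested-model comparison and Benjamini-Hochberg adjustment."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from miracle import (
    ClinicalTable,
    SurvivalFit,
    bh_adjust,
    compare_models,
    cox_fit,
    model_specs,
    stratify_cohorts,
)
from miracle.errors import (
    ContractError,
    DegenerateDataError,
    NonIdentifiableError,
    StratificationError,
    ValidationError,
)
from miracle.synthetic import SimulationConfig, simulate_cohorts


def efron_loglik(beta: float, times, events, x) -> float:
    """Independent Efron partial log-likelihood for one covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    ll = 0.0
    for ut in np.unique(times[events == 1]):
        dead = (times == ut) & (events == 1)
        at_risk = times >= ut
        d = int(dead.sum())
        sum_theta_d = theta[dead].sum()
        sum_theta_r = theta[at_risk].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(sum_theta_r - (ell / d) * sum_theta_d)
    return ll


def grid_beta(times, events, x, lo=-5.0, hi=5.0, n=20001) -> float:
    grid = np.linspace(lo, hi, n)
    lls = [efron_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def clinical_from(times, events, cohort="A", **covs) -> ClinicalTable:
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(times))],
            "cohort": cohort,
            "time": times,
            "event": events,
            **covs,
        }
    )
    return ClinicalTable(df)


def predictor_series(values) -> pd.Series:
    return pd.Series(values, index=[f"S{i}" for i in range(len(values))], dtype=float)


SMALL_FIXTURES = [
    # (times, events, x): all-events alternating covariate
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [0, 1, 0, 1, 0, 1]),
    # tied event times
    ([1, 1, 2, 3, 3, 4, 5], [1, 1, 1, 0, 1, 1, 1], [0.2, 1.1, -0.5, 0.8, 0.0, 1.5, -1.0]),
    # censoring mixed in
    ([3, 1, 4, 1, 5, 9, 2, 6], [1, 0, 1, 1, 0, 1, 1, 0], [0.5, -0.2, 1.0, 0.1, -1.1, 0.7, 0.3, -0.4]),
    # ten subjects, continuous covariate
    (
        [2, 4, 4, 7, 8, 10, 11, 13, 15, 16],
        [1, 1, 1, 0, 1, 1, 0, 1, 1, 1],
        [0.9, -0.3, 0.4, 1.2, -0.8, 0.1, 0.6, -1.4, 0.2, 0.5],
    ),
]


class TestCoxFit:
    @pytest.mark.parametrize("times,events,x", SMALL_FIXTURES)
    def test_beta_matches_efron_grid_oracle(self, times, events, x):
        fit = cox_fit(clinical_from(times, events), predictor_series(x))
        assert fit.beta == pytest.approx(grid_beta(times, events, x), abs=1e-3)

    def test_negating_predictor_negates_beta(self):
        times, events, x = SMALL_FIXTURES[3]
        fit = cox_fit(clinical_from(times, events), predictor_series(x))
        neg = cox_fit(clinical_from(times, events), predictor_series([-v for v in x]))
        assert neg.beta == pytest.approx(-fit.beta, abs=1e-8)

    def test_hr_within_confidence_interval(self):
        times, events, x = SMALL_FIXTURES[3]
        fit = cox_fit(clinical_from(times, events), predictor_series(x))
        assert fit.ci_low <= fit.hr <= fit.ci_high
        assert fit.hr == pytest.approx(np.exp(fit.beta))

    def test_constant_predictor_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            cox_fit(clinical_from([1, 2, 3, 4], [1, 1, 1, 1]), predictor_series([2, 2, 2, 2]))

    def test_too_few_events(self):
        with pytest.raises(DegenerateDataError):
            cox_fit(clinical_from([1, 2, 3, 4], [0, 0, 0, 1]), predictor_series([1, 2, 3, 4]))


class TestStratifyCohorts:
    def _fake_fit(self, hr, p):
        return SurvivalFit("icr_nes", np.log(hr), hr, hr / 2, hr * 2, p, -10.0, 50, 20)

    def test_threshold_classification(self, monkeypatch):
        fits = {"A": self._fake_fit(0.5, 0.05), "B": self._fake_fit(1.8, 0.2), "C": self._fake_fit(1.6, 0.01)}
        monkeypatch.setattr(
            "miracle.survival.cox_fit",
            lambda clinical, nes, predictor_name: fits[clinical.data["cohort"].iloc[0]],
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(30)],
                    "cohort": ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                    "time": np.arange(1, 31),
                    "event": [1] * 30,
                }
            )
        )
        nes = pd.Series(np.linspace(0, 1, 30), index=clin.sample_ids)
        strat = stratify_cohorts(clin, nes)
        assert strat.classes == {"A": "IE", "B": "neutral", "C": "ID"}

    def test_low_event_cohort_excluded(self):
        clin = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(40)],
                    "cohort": ["A"] * 20 + ["B"] * 20,
                    "time": np.arange(1, 41),
                    "event": [1] * 20 + [0] * 18 + [1] * 2,
                }
            )
        )
        rng = np.random.default_rng(0)
        nes = pd.Series(rng.uniform(size=40), index=clin.sample_ids)
        strat = stratify_cohorts(clin, nes, min_events=5)
        assert "B" in strat.excluded
        assert "B" not in strat.classes

    def test_single_cohort_rejected(self):
        clin = clinical_from([1, 2, 3], [1, 1, 1])
        with pytest.raises(StratificationError):
            stratify_cohorts(clin, predictor_series([0.1, 0.2, 0.3]))

    def test_planted_archetypes_recovered(self, default_sim, discovery):
        truth = default_sim.truth.archetype_of
        assert discovery.stratification.classes == truth


class TestCompareModels:
    def test_model_compared_to_itself_is_null(self, default_sim, discovery):
        specs = model_specs("score")
        predictor = discovery.scores["log2_score"]
        res = compare_models(default_sim.clinical, predictor, specs["Model1"], specs["Model1"])
        assert (res.chi2, res.df, res.p) == (0.0, 0, 1.0)

    def test_non_nested_specs_rejected(self, default_sim, discovery):
        specs = model_specs("score")
        with pytest.raises(ContractError):
            compare_models(
                default_sim.clinical, discovery.scores["log2_score"], specs["Model1"], specs["Model2"]
            )

    def test_true_predictor_improves_on_clinical_covariates(self, default_sim, discovery):
        # Model 2 (score + cohort + clinical) vs Model 3 (clinical only)
        specs = model_specs("score")
        res = compare_models(
            default_sim.clinical, discovery.scores["log2_score"], specs["Model2"], specs["Model3"]
        )
        assert res.df == 1
        assert res.p < 0.01

    def test_noise_covariates_do_not_help(self):
        # Model 1 vs Model 2 where age/gender/stage are independent of hazard:
        # the LRT p-value should look null across seeds
        cfg_base = SimulationConfig(n_genes=30, samples_per_cohort=84, n_icr_genes=5,
                                    n_ie_genes=5, n_id_genes=5)
        specs = model_specs("score")
        null_ps = []
        for seed in range(50):
            sim = simulate_cohorts(replace(cfg_base, seed=1000 + seed))
            predictor = pd.Series(sim.truth.balance, index=sim.truth.sample_ids)
            res = compare_models(sim.clinical, predictor, specs["Model2"], specs["Model1"])
            null_ps.append(res.p)
        assert np.mean(np.array(null_ps) > 0.01) >= 0.9


from hypothesis import given, settings
from hypothesis import strategies as st


class TestBhAdjust:
    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_dominates_input_and_preserves_order_relation(self, pvals):
        adjusted = bh_adjust(pvals)
        assert (adjusted >= np.asarray(pvals) - 1e-15).all()
        assert (adjusted <= 1.0).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    def test_step_up_worked_example(self):
        # hand computation: (0.01*3/1, 0.02*3/2, 0.04*3/3) with step-up -> (0.03, 0.03, 0.04)
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    def test_matches_statsmodels_and_bounds(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)
            assert (ours >= p - 1e-15).all() and (ours <= 1.0).all()
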