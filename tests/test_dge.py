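"""Tertile grouping and Wilcoxon differential expression."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from miracle import DEGThresholds, ExpressionMatrix, filter_degs, tertile_groups, wilcoxon_de
from miracle.errors import ContractError, DegenerateDataError


def exact_ranksum_p(high, low) -> float:
    """Enumeration oracle: two-sided rank-sum p over all group assignments."""
    from scipy.stats import rankdata

    combined = np.concatenate([high, low])
    ranks = rankdata(combined)
    n_high = len(high)
    observed = ranks[:n_high].sum()
    null = [sum(ranks[list(idx)]) for idx in combinations(range(len(combined)), n_high)]
    mean = np.mean(null)
    extreme = sum(abs(w - mean) >= abs(observed - mean) - 1e-12 for w in null)
    return extreme / len(null)


def matrix_from(rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(list(rows), samples, np.array(list(rows.values()), float))


class TestTertileGroups:
    def test_nine_samples_split_three_three(self):
        nes = pd.Series(range(1, 10), index=[f"S{i}" for i in range(1, 10)], dtype=float)
        low, high = tertile_groups(nes)
        assert low == ["S1", "S2", "S3"]
        assert high == ["S7", "S8", "S9"]

    def test_floor_rule_with_ten_samples(self):
        nes = pd.Series(range(10), index=[f"S{i}" for i in range(10)], dtype=float)
        low, high = tertile_groups(nes)
        assert len(low) == len(high) == 3

    def test_all_equal_scores_fall_back_to_id_order(self, caplog):
        nes = pd.Series(1.0, index=["S3", "S1", "S2"])
        with caplog.at_level("WARNING"):
            low, high = tertile_groups(nes)
        assert low == ["S1"] and high == ["S3"]
        assert "identical" in caplog.text

    def test_too_few_samples(self):
        with pytest.raises(DegenerateDataError):
            tertile_groups(pd.Series([1.0, 2.0], index=["a", "b"]))


class TestWilcoxonDE:
    def test_exact_worked_example(self):
        # fully separated 3 vs 3: 2 of the 20 assignments are as extreme
        samples = [f"H{i}" for i in range(3)] + [f"L{i}" for i in range(3)]
        expr = matrix_from({"G1": [10, 11, 12, 1, 2, 3]}, samples)
        table = wilcoxon_de(expr, low_ids=samples[3:], high_ids=samples[:3])
        assert table.loc["G1", "p"] == pytest.approx(0.1)
        assert table.loc["G1", "p"] == pytest.approx(
            exact_ranksum_p(np.array([10, 11, 12]), np.array([1, 2, 3]))
        )

    def test_matches_enumeration_oracle(self, rng):
        high = rng.normal(1, 1, size=4)
        low = rng.normal(0, 1, size=5)
        samples = [f"S{i}" for i in range(9)]
        expr = matrix_from({"G1": np.concatenate([high, low]).tolist()}, samples)
        table = wilcoxon_de(expr, low_ids=samples[4:], high_ids=samples[:4])
        assert table.loc["G1", "p"] == pytest.approx(exact_ranksum_p(high, low), abs=1e-12)

    def test_constant_gene_gets_p_one(self):
        samples = [f"S{i}" for i in range(6)]
        expr = matrix_from({"G1": [2, 2, 2, 2, 2, 2], "G2": [9, 9, 9, 1, 1, 1]}, samples)
        table = wilcoxon_de(expr, low_ids=samples[3:], high_ids=samples[:3])
        assert table.loc["G1", "p"] == 1.0
        assert table.loc["G1", "log2fc"] == 0.0

    def test_p_invariant_under_monotone_transform(self, rng):
        values = rng.lognormal(size=(6, 30))
        samples = [f"S{i}" for i in range(30)]
        expr = ExpressionMatrix([f"G{i}" for i in range(6)], samples, values)
        expr2 = ExpressionMatrix(expr.gene_ids, samples, np.log1p(values))
        t1 = wilcoxon_de(expr, samples[:12], samples[18:])
        t2 = wilcoxon_de(expr2, samples[:12], samples[18:], log_scale=True)
        np.testing.assert_allclose(t1["p"], t2["p"], atol=1e-12)

    def test_exact_and_asymptotic_branches_agree(self, rng):
        # tie-free instances at the exact branch's upper size limit
        for _ in range(10):
            high = rng.normal(0.5, 1, size=10)
            low = rng.normal(0, 1, size=10)
            p_exact = exact_ranksum_p(high, low)
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(high, low, alternative="two-sided", method="asymptotic").pvalue
            assert p_asym == pytest.approx(p_exact, abs=0.01)

    def test_log_scale_fold_change_is_mean_difference(self):
        samples = [f"S{i}" for i in range(6)]
        expr = matrix_from({"G1": [5, 6, 7, 1, 2, 3]}, samples)
        table = wilcoxon_de(expr, samples[3:], samples[:3], log_scale=True)
        assert table.loc["G1", "log2fc"] == pytest.approx(4.0)

    def test_rank_is_permutation_and_fdr_dominates_p(self, rng):
        values = rng.lognormal(size=(40, 24))
        samples = [f"S{i}" for i in range(24)]
        expr = ExpressionMatrix([f"G{i:02d}" for i in range(40)], samples, values)
        table = wilcoxon_de(expr, samples[:10], samples[14:])
        assert sorted(table["rank"]) == list(range(1, 41))
        assert (table["fdr"] >= table["p"] - 1e-15).all()

    def test_overlapping_groups_rejected(self):
        samples = [f"S{i}" for i in range(6)]
        expr = matrix_from({"G1": [1, 2, 3, 4, 5, 6]}, samples)
        with pytest.raises(ContractError):
            wilcoxon_de(expr, samples[:3], samples[2:])


class TestFilterDegs:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {
                "log2fc": [1.5, 1.5, 0.8, 2.5],
                "p": [0.01, 0.01, 0.001, 0.2],
                "fdr": [0.05, 0.2, 0.01, 0.4],
                "rank": [1, 2, 3, 4],
            },
            index=pd.Index(["A", "B", "C", "D"], name="gene"),
        )

    def test_default_thresholds(self, table):
        gs = filter_degs(table)
        assert gs.genes == ("A",)

    def test_empty_result_is_none_not_error(self, table):
        assert filter_degs(table, DEGThresholds(log2fc=10.0)) is None

    def test_relaxing_thresholds_gives_superset(self, table):
        tight = filter_degs(table)
        loose = filter_degs(table, DEGThresholds(log2fc=0.5, p=0.05, fdr=0.3))
        assert set(tight.genes) <= set(loose.genes)

    def test_non_strict_inequalities(self, table):
        table.loc["E"] = [1.0, 0.05, 0.1, 5]
        assert "E" not in (filter_degs(table) or ())
        loose = filter_degs(table, DEGThresholds(strict=False))
        assert "E" in loose.genes
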