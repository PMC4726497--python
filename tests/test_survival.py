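"""Signature construction, scoring, ortholog mapping and log-rank stratification."""

import numpy as np
import pandas as pd
import pytest

from cnotscreen.simulate import SimulationConfig, simulate_cohort
from cnotscreen.survival import (
    GeneSignature,
    SurvivalCohort,
    build_signature,
    map_orthologs,
    score_patients,
    stratify_logrank,
)

from _oracles import hand_logrank_chi2
from conftest import make_matrix


def cohort_from(times, events, expr=None, n_genes=1):
    n = len(times)
    ids = [f"p{i}" for i in range(n)]
    clinical = pd.DataFrame({"time": times, "event": events}, index=ids)
    if expr is None:
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((n, n_genes)),
                            index=ids, columns=[f"G{i}" for i in range(n_genes)])
    else:
        expr.index = ids
    return SurvivalCohort(clinical, expr)


class TestBuildSignature:
    def test_gene_identical_to_driver_gets_weight_minus_one(self):
        m = make_matrix(3, 3, None, noise_sd=0.5, seed=1)
        m.values.loc["g1"] = m.values.loc["Cnot7"] = np.arange(9, dtype=float)
        sig = build_signature({"g1"}, m, driver="Cnot7")
        assert sig.entries["g1"] == pytest.approx(-1.0)

    def test_mirrored_gene_gets_weight_plus_one(self):
        m = make_matrix(3, 3, None, noise_sd=0.5, seed=2)
        m.values.loc["Cnot7"] = np.arange(9, dtype=float)
        m.values.loc["g1"] = -np.arange(9, dtype=float)
        sig = build_signature({"g1"}, m, driver="Cnot7")
        assert sig.entries["g1"] == pytest.approx(1.0)

    def test_zero_variance_gene_excluded_with_warning(self, caplog):
        m = make_matrix(3, 3, None, noise_sd=0.5, seed=3)
        m.values.loc["Cnot7"] = np.arange(9, dtype=float)
        m.values.loc["g1"] = 5.0
        with caplog.at_level("WARNING"):
            sig = build_signature({"g1", "g2"}, m, driver="Cnot7")
        assert "g1" not in sig.entries and "g2" in sig.entries

    def test_planted_anticorrelated_genes_get_positive_weights(self):
        from cnotscreen.simulate import simulate_expression

        cfg = SimulationConfig(seed=4, n_genes=1000, n_planted_anticorr=100,
                               effect_size_delta=1.5, noise_sd=0.5)
        matrix, truth = simulate_expression(cfg)
        sig = build_signature(truth, matrix, driver="Cnot7")
        assert np.mean([w > 0 for w in sig.entries.values()]) >= 0.99


class TestMapOrthologs:
    def test_empty_map_drops_everything(self):
        sig = GeneSignature({"Tob1": 1.0, "Cpeb2": 0.5})
        mapped, coverage = map_orthologs(sig, {})
        assert mapped is None and coverage == 0.0

    def test_identity_style_mapping_retains_weight(self):
        sig = GeneSignature({"Tob1": 0.8})
        mapped, coverage = map_orthologs(sig, {"Tob1": "TOB1"})
        assert mapped.entries == {"TOB1": 0.8} and coverage == 1.0

    def test_partial_coverage_fraction_matches_printed_style(self):
        from cnotscreen.screen import percent

        sig = GeneSignature({f"g{i}": 1.0 for i in range(71)})
        omap = {f"g{i}": f"G{i}" for i in range(46)}
        mapped, coverage = map_orthologs(sig, omap)
        assert len(mapped.entries) == 46
        assert coverage == pytest.approx(46 / 71)
        assert percent(46, 71) == "65%"

    def test_collision_keeps_larger_weight(self, caplog):
        sig = GeneSignature({"a": 0.2, "b": -0.9})
        with caplog.at_level("WARNING"):
            mapped, _ = map_orthologs(sig, {"a": "X", "b": "X"})
        assert mapped.entries == {"X": -0.9}


class TestScorePatients:
    def test_single_gene_score_is_its_zscore(self):
        sig = GeneSignature({"G0": 1.0})
        cohort = cohort_from([1, 2, 3, 4], [1, 1, 1, 1])
        scores = score_patients(sig, cohort)
        z = (cohort.expression["G0"] - cohort.expression["G0"].mean()) \
            / cohort.expression["G0"].std(ddof=0)
        assert np.allclose(scores, z)

    def test_negating_weights_negates_scores(self):
        sig = GeneSignature({"G0": 0.7, "G1": -0.2})
        neg = GeneSignature({"G0": -0.7, "G1": 0.2})
        cohort = cohort_from(range(1, 9), [1] * 8, n_genes=2)
        assert np.allclose(score_patients(sig, cohort),
                           -score_patients(neg, cohort))

    def test_constant_shift_of_one_gene_leaves_scores_unchanged(self):
        sig = GeneSignature({"G0": 0.7, "G1": 0.3})
        cohort = cohort_from(range(1, 9), [1] * 8, n_genes=2)
        shifted_expr = cohort.expression.copy()
        shifted_expr["G0"] += 100.0
        shifted = SurvivalCohort(cohort.clinical, shifted_expr)
        assert np.allclose(score_patients(sig, cohort),
                           score_patients(sig, shifted))

    def test_missing_genes_excluded_with_renormalization(self):
        sig = GeneSignature({"G0": 1.0, "ABSENT": 5.0})
        cohort = cohort_from([1, 2, 3, 4], [1, 1, 1, 1])
        scores = score_patients(sig, cohort)
        only = score_patients(GeneSignature({"G0": 1.0}), cohort)
        assert np.allclose(scores, only)

    def test_no_overlap_is_an_error(self):
        sig = GeneSignature({"ABSENT": 1.0})
        cohort = cohort_from([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="no signature genes"):
            score_patients(sig, cohort)


class TestStratifyLogrank:
    def test_identical_groups_give_null_result(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1] * 8
        cohort = cohort_from(times, events)
        scores = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=cohort.clinical.index,
                           dtype=float)
        res = stratify_logrank(scores, cohort)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_logrank(self):
        # group A times (1,2,3), group B (4,5,6), all events
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        cohort = cohort_from(times, events)
        scores = pd.Series([2, 2, 2, 1, 1, 1], index=cohort.clinical.index,
                           dtype=float)
        res = stratify_logrank(scores, cohort)
        oracle = hand_logrank_chi2(
            np.array([1.0, 2, 3]), np.ones(3, dtype=int),
            np.array([4.0, 5, 6]), np.ones(3, dtype=int),
        )
        assert res.chi_square == pytest.approx(oracle, abs=1e-10)

    def test_hand_recursion_on_censored_data(self):
        times = np.array([1, 2, 2, 3, 5, 6, 7, 9, 4, 4], dtype=float)
        events = np.array([1, 0, 1, 1, 1, 0, 1, 1, 1, 0])
        cohort = cohort_from(times, events)
        scores = pd.Series([3, 3, 3, 3, 3, 1, 1, 1, 1, 1],
                           index=cohort.clinical.index, dtype=float)
        res = stratify_logrank(scores, cohort)
        oracle = hand_logrank_chi2(times[:5], events[:5], times[5:], events[5:])
        assert res.chi_square == pytest.approx(oracle, abs=1e-10)

    def test_median_split_balanced_for_distinct_scores(self):
        for n in (8, 9):
            cohort = cohort_from(range(1, n + 1), [1] * n)
            scores = pd.Series(np.arange(n, dtype=float),
                               index=cohort.clinical.index)
            res = stratify_logrank(scores, cohort)
            n_high = (res.labels == "high").sum()
            n_low = (res.labels == "low").sum()
            assert abs(n_high - n_low) <= 1

    def test_median_ties_assigned_to_low_group(self):
        scores_vals = [1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0, 7.0, 8.0]
        cohort = cohort_from(range(1, 10), [1] * 9)
        scores = pd.Series(scores_vals, index=cohort.clinical.index)
        res = stratify_logrank(scores, cohort)
        assert (res.labels[scores == scores.median()] == "low").all()

    def test_label_swap_symmetry(self):
        cohort = cohort_from([1, 3, 5, 7, 2, 4, 6, 8], [1, 1, 0, 1, 1, 0, 1, 1])
        s = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=cohort.clinical.index,
                      dtype=float)
        r1 = stratify_logrank(s, cohort)
        r2 = stratify_logrank(-s, cohort)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)

    def test_degenerate_split_rejected(self):
        cohort = cohort_from([1, 2, 3], [1, 1, 1])
        scores = pd.Series([1.0, 1.0, 1.0], index=cohort.clinical.index)
        with pytest.raises(ValueError):
            stratify_logrank(scores, cohort)


def test_protective_hazard_separates_groups():
    sig = GeneSignature({f"G{i}": 1.0 for i in range(5)})
    cfg = SimulationConfig(seed=42, cohort_n=600, hazard_beta=-0.7)
    cohort = simulate_cohort(sig, cfg)
    scores = score_patients(sig, cohort)
    res = stratify_logrank(scores, cohort)
    assert res.p_value < 0.001
    high, low = res.group_stats.loc["high"], res.group_stats.loc["low"]
    assert high["median_survival"] > low["median_survival"]
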