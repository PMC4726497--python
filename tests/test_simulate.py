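"""Synthetic-data generators: planted truth, determinism, distributional oracles."""

import numpy as np
import pandas as pd
import pytest

from cnotscreen.motifs import MotifDefinition, default_motifs
from cnotscreen.scan import scan_sequence
from cnotscreen.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_expression,
    simulate_ortholog_map,
    simulate_rip,
    simulate_utrs,
)
from cnotscreen.survival import GeneSignature


CPSF = MotifDefinition("CPSF", ("AAUAAA",))


def test_prevalence_one_plants_a_site_in_every_gene():
    cfg = SimulationConfig(seed=3, n_genes=50, motif_prevalence={"CPSF": 1.0},
                           utr_length_mean=120, utr_length_sd=10)
    utrs, truth = simulate_utrs(cfg, [CPSF])
    assert set(truth["gene_id"]) == {u.gene_id for u in utrs}
    # planted site is really present at the recorded position
    seqs = {u.gene_id: u.sequence for u in utrs}
    for row in truth.itertuples():
        assert seqs[row.gene_id][row.start:row.end] == row.planted_seq == "AAUAAA"


def test_identical_config_gives_identical_outputs():
    cfg = SimulationConfig(seed=11, n_genes=40)
    motifs = default_motifs()
    utrs1, truth1 = simulate_utrs(cfg, motifs)
    utrs2, truth2 = simulate_utrs(cfg, motifs)
    assert utrs1 == utrs2
    pd.testing.assert_frame_equal(truth1, truth2)
    counts1, t1 = simulate_rip(cfg)
    counts2, t2 = simulate_rip(cfg)
    pd.testing.assert_frame_equal(counts1, counts2)
    assert t1 == t2


def test_observed_presence_matches_planting_plus_chance_rate():
    # 6-mer at prevalence 0.5 on uniform-composition 200-mers: presence
    # fraction = 0.5 + 0.5*chance, chance = 1-(1-(1/4)**6)**(L-5)
    motif = MotifDefinition("M6", ("AACGUA",))
    L, n = 200, 200
    cfg = SimulationConfig(seed=5, n_genes=n, utr_length_mean=L, utr_length_sd=0,
                           base_composition=(0.25, 0.25, 0.25, 0.25),
                           motif_prevalence={"M6": 0.5})
    utrs, truth = simulate_utrs(cfg, [motif])
    present = np.array([len(scan_sequence(u, motif)) > 0 for u in utrs])
    chance = 1 - (1 - 0.25**6) ** (L - 5)
    expected = 0.5 + 0.5 * chance
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(present.mean() - expected) < 3 * se + 0.5 / n
    assert present.mean() >= len(set(truth["gene_id"])) / n


def test_motif_longer_than_utr_raises_naming_gene():
    cfg = SimulationConfig(seed=1, n_genes=3, utr_length_mean=20, utr_length_sd=0,
                           motif_prevalence={"long": 1.0})
    long_motif = MotifDefinition("long", ("AUCG" * 8,))
    with pytest.raises(ValueError, match="gene00000"):
        simulate_utrs(cfg, [long_motif])


def test_planted_sites_do_not_overlap():
    cfg = SimulationConfig(seed=9, n_genes=100, utr_length_mean=150, utr_length_sd=0,
                           motif_prevalence={"CPE": 1.0, "PUM": 1.0, "NRE": 1.0,
                                             "CPSF": 1.0, "ARE_permissive": 1.0,
                                             "ARE_stringent": 1.0})
    _, truth = simulate_utrs(cfg, default_motifs())
    for _, rows in truth.groupby("gene_id"):
        iv = sorted(zip(rows["start"], rows["end"]))
        assert all(a[1] <= b[0] for a, b in zip(iv, iv[1:]))


def test_zero_delta_gives_empty_truth_and_null_means():
    cfg = SimulationConfig(seed=2, n_genes=400, effect_size_delta=0.0,
                           noise_sd=0.3, n_per_group=6)
    matrix, truth = simulate_expression(cfg)
    assert truth == set()
    ctrl = matrix.values[matrix.samples_in("control")].mean(axis=1)
    kd = matrix.values[matrix.samples_in("knockdown")].mean(axis=1)
    diffs = (kd - ctrl).drop("Cnot7")
    assert abs(diffs.mean()) < 3 * 0.3 * np.sqrt(2 / 6) / np.sqrt(400)


def test_noiseless_limit_shifts_are_exact():
    cfg = SimulationConfig(seed=2, n_genes=50, n_planted_anticorr=1,
                           effect_size_delta=1.0, noise_sd=0.0, n_per_group=2)
    matrix, truth = simulate_expression(cfg)
    (g,) = truth
    row = matrix.values.loc[g]
    kd = row[matrix.samples_in("knockdown")].mean()
    ctrl = row[matrix.samples_in("control")].mean()
    oe = row[matrix.samples_in("overexpression")].mean()
    assert kd - ctrl == pytest.approx(1.0, abs=1e-12)
    assert oe - ctrl == pytest.approx(-1.0, abs=1e-12)


def test_planted_welch_t_matches_noncentral_expectation():
    # planted |t| should center on the simulation-oracle mean for
    # delta=1.5, sd=0.5, n=4 (ncp = 1.5/(0.5*sqrt(2/4)) ~ 4.24)
    from scipy import stats

    cfg = SimulationConfig(seed=4, n_genes=3000, n_planted_anticorr=600,
                           effect_size_delta=1.5, noise_sd=0.5, n_per_group=4)
    matrix, truth = simulate_expression(cfg)
    kd = matrix.values.loc[sorted(truth), matrix.samples_in("knockdown")].to_numpy()
    ctrl = matrix.values.loc[sorted(truth), matrix.samples_in("control")].to_numpy()
    t_obs, _ = stats.ttest_ind(kd, ctrl, axis=1, equal_var=False)

    rng = np.random.default_rng(12345)  # independent oracle draw
    a = rng.normal(1.5, 0.5, (20000, 4))
    b = rng.normal(0.0, 0.5, (20000, 4))
    t_oracle, _ = stats.ttest_ind(a, b, axis=1, equal_var=False)
    se = np.sqrt(np.var(t_oracle) / len(t_obs) + np.var(t_oracle) / len(t_oracle))
    assert abs(np.abs(t_obs).mean() - np.abs(t_oracle).mean()) < 3 * se


def test_rip_fold_one_has_empty_truth():
    cfg = SimulationConfig(seed=6, n_genes=100, rip_fold=1.0)
    _, truth = simulate_rip(cfg)
    assert truth == set()


def test_rip_poisson_limit_recovers_fold():
    cfg = SimulationConfig(seed=8, n_genes=4000, rip_dispersion=0.0, rip_fold=4.0,
                           rip_mean=100.0, rip_frac_enriched=0.25)
    counts, truth = simulate_rip(cfg)
    sub = counts.loc[sorted(truth)]
    ratio = sub["ip_flag"].sum() / sub["input"].sum()
    # Poisson SE of the aggregate ratio
    se = ratio * np.sqrt(1 / sub["ip_flag"].sum() + 1 / sub["input"].sum())
    assert abs(ratio - 4.0) < 3 * se


def test_rip_negative_dispersion_rejected():
    with pytest.raises(ValueError, match="dispersion"):
        SimulationConfig(rip_dispersion=-0.1)


def test_cohort_null_beta_gives_independent_score_and_time():
    sig = GeneSignature({f"G{i}": 1.0 for i in range(10)})
    cfg = SimulationConfig(seed=13, cohort_n=2000, hazard_beta=0.0,
                           censor_rate=0.0, follow_up_max=np.inf)
    cohort = simulate_cohort(sig, cfg)
    z = (cohort.expression - cohort.expression.mean()) / cohort.expression.std(ddof=0)
    score = z.mean(axis=1)
    r = np.corrcoef(score, np.log(cohort.clinical["time"]))[0, 1]
    assert abs(r) < 3 / np.sqrt(2000)


def test_cohort_no_censoring_all_events_observed():
    sig = GeneSignature({"G0": 1.0})
    cfg = SimulationConfig(seed=14, cohort_n=200, censor_rate=0.0,
                           follow_up_max=np.inf)
    cohort = simulate_cohort(sig, cfg)
    assert (cohort.clinical["event"] == 1).all()


def test_protective_signature_prolongs_high_score_survival():
    sig = GeneSignature({f"G{i}": 1.0 for i in range(5)})
    wins = 0
    for seed in range(100):
        cfg = SimulationConfig(seed=seed, cohort_n=200, hazard_beta=-0.7,
                               censor_rate=0.0, follow_up_max=np.inf)
        cohort = simulate_cohort(sig, cfg)
        z = (cohort.expression - cohort.expression.mean()) / cohort.expression.std(ddof=0)
        score = z.mean(axis=1)
        high = score > score.median()
        t = cohort.clinical["time"]
        wins += t[high.values].median() >= t[~high.values].median()
    assert wins >= 95  # monotone-hazard property, allowing sampling noise


def test_ortholog_map_coverage_and_determinism():
    genes = [f"gene{i:05d}" for i in range(500)]
    m1 = simulate_ortholog_map(genes, coverage=0.74, seed=5)
    m2 = simulate_ortholog_map(genes, coverage=0.74, seed=5)
    assert m1 == m2
    assert len(m1) == 370
    assert all(v == k.upper() for k, v in m1.items())
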