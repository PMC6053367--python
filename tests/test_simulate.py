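"""Generator contracts: determinism, bounds, ground-truth bookkeeping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import agesplice as ag
from agesplice.containers import SENTINEL
from agesplice.motifs import count_occurrences


def test_cohort_basic_and_deterministic():
    cfg = ag.SimulationConfig(n_individuals=100, age_range=(20, 70), seed=1)
    c1 = ag.simulate_cohort(cfg)
    c2 = ag.simulate_cohort(cfg)
    assert len(c1) == 100
    assert ((c1.ages >= 20) & (c1.ages <= 70)).all()
    assert set(c1.genders.unique()) <= {0, 1}
    pd.testing.assert_frame_equal(c1.table, c2.table)


def test_cohort_mean_age_law_of_large_numbers():
    # uniform(20, 70) has mean 45; n = 10000 keeps the sample mean within +-1
    cfg = ag.SimulationConfig(n_individuals=10_000, n_events=1, seed=7)
    cohort = ag.simulate_cohort(cfg)
    assert abs(cohort.ages.mean() - 45.0) < 1.0


@pytest.mark.parametrize(
    "bad",
    [
        {"n_individuals": 0},
        {"age_range": (70, 20)},
        {"frac_age_assoc": 1.5},
        {"missing_rate": 1.0},
        {"noise_sd": -0.1},
        {"planted_driver": ("M_PTBP1", "nowhere", "up")},
        {"planted_driver": ("nope", "cassette_exon", "up")},
    ],
)
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        ag.SimulationConfig(**bad)


def test_psi_bounds_sentinels_and_truth_bookkeeping(small_dataset, small_config):
    v = small_dataset.psi.values.to_numpy()
    ok = ((v >= 0) & (v <= 1)) | (v == SENTINEL)
    assert ok.all()
    assert (v == SENTINEL).any()
    truth = small_dataset.truth.events
    assert truth["is_age_assoc"].sum() == round(
        small_config.frac_age_assoc * small_config.n_events
    )
    # trend class consistent with the sign of the planted coefficient
    assert (truth.loc[truth.beta_age > 0, "trend_class"] == "up").all()
    assert (truth.loc[truth.beta_age < 0, "trend_class"] == "down").all()
    assert (truth.loc[~truth.is_age_assoc, "trend_class"] == "stable").all()


def test_dataset_determinism(small_config):
    d1 = ag.simulate_dataset(small_config)
    d2 = ag.simulate_dataset(small_config)
    pd.testing.assert_frame_equal(d1.psi.values, d2.psi.values)
    pd.testing.assert_frame_equal(d1.gene_expr, d2.gene_expr)
    pd.testing.assert_series_equal(
        d1.cohort.table["disease"], d2.cohort.table["disease"]
    )
    e = next(iter(d1.regions))
    assert d1.regions[e].sequences == d2.regions[e].sequences


def test_degenerate_psi_constant_rows():
    cfg = ag.SimulationConfig(
        n_individuals=30, n_events=10, frac_age_assoc=0.5, effect_size=0.0,
        noise_sd=0.0, n_hidden_factors=0, gender_effect_sd=0.0,
        missing_rate=0.0, seed=2,
    )
    cohort = ag.simulate_cohort(cfg)
    psi, _ = ag.simulate_psi(cohort, cfg)
    assert (psi.values.nunique(axis=1) == 1).all()


def test_flagged_event_correlation_sign_matches_planted_beta():
    cfg = ag.SimulationConfig(
        n_individuals=80, n_events=20, frac_age_assoc=0.5, effect_size=0.05,
        noise_sd=0.0, n_hidden_factors=0, gender_effect_sd=0.0,
        missing_rate=0.0, seed=3,
    )
    cohort = ag.simulate_cohort(cfg)
    psi, truth = ag.simulate_psi(cohort, cfg)
    ages = cohort.ages.to_numpy()
    for eid in truth.events.index[truth.events.is_age_assoc]:
        r = stats.pearsonr(psi.values.loc[eid], ages).statistic
        assert np.sign(r) == np.sign(truth.events.loc[eid, "beta_age"])


def test_expression_gene_is_exact_transcript_sum(small_dataset):
    ds = small_dataset
    summed = ds.tx_expr.groupby(ds.tx2gene, sort=False).sum().loc[ds.gene_expr.index]
    assert np.array_equal(ds.gene_expr.to_numpy(), summed.to_numpy())


def test_expression_degenerate_constant():
    cfg = ag.SimulationConfig(
        n_individuals=25, n_genes=10, expr_frac_age_assoc=0.0,
        frac_isoform_switch=0.0, expr_noise_sd=0.0, ratio_noise_sd=0.0,
        n_hidden_factors=0, seed=4,
    )
    cohort = ag.simulate_cohort(cfg)
    gene, tx, _ = ag.simulate_expression(cohort, cfg)
    assert (gene.nunique(axis=1) == 1).all()
    assert (tx.nunique(axis=1) == 1).all()


def test_switch_genes_have_flat_totals_but_trending_ratios():
    cfg = ag.SimulationConfig(
        n_individuals=200, n_genes=50, expr_frac_age_assoc=0.0,
        frac_isoform_switch=0.2, expr_noise_sd=0.1, ratio_noise_sd=0.0,
        n_hidden_factors=0, switch_effect_size=0.02, seed=5,
    )
    cohort = ag.simulate_cohort(cfg)
    gene, tx, truth = ag.simulate_expression(cohort, cfg)
    ages = cohort.ages.to_numpy()
    switch = truth.genes.index[truth.genes.is_switch]
    assert len(switch) == 10
    for g in switch:
        r_gene = stats.pearsonr(np.log2(gene.loc[g] + 1), ages).statistic
        assert abs(r_gene) < 0.3  # total planted flat (residual noise only)
        r_tx = max(
            abs(stats.pearsonr(np.log2(tx.loc[t] + 1), ages).statistic)
            for t in truth.transcripts.index[truth.transcripts.gene == g]
        )
        assert r_tx > 0.7  # the ratio shift moves the transcripts


def test_planted_motif_enriched_in_target_class_and_region(small_dataset):
    ds = small_dataset
    motif_id, region, klass = ds.config.planted_driver
    motif = next(m for m in ds.config.motif_set if m.motif_id == motif_id)
    trend = ds.truth.events["trend_class"]
    counts = {
        k: np.mean([
            count_occurrences(ds.regions[e][region], motif.consensus)
            for e in trend.index[trend == k]
        ])
        for k in ("up", "stable")
    }
    assert counts[klass] > counts["stable"] + 1.0


def test_sf_expression_trend_sign():
    cfg = ag.SimulationConfig(n_individuals=60, n_events=20, sf_noise_sd=0.0, seed=6)
    cohort = ag.simulate_cohort(cfg)
    trend = pd.Series("stable", index=[f"e{i}" for i in range(20)])
    _, sf = ag.simulate_regions_and_sf(cohort, trend, cfg)
    driver_sf = next(
        m.sf_gene for m in cfg.motif_set if m.motif_id == cfg.planted_driver[0]
    )
    ages = cohort.ages.to_numpy()
    slope = np.polyfit(ages, np.log2(sf.loc[driver_sf].to_numpy()), 1)[0]
    # inclusion-up driver is a repressor whose expression falls with age
    assert slope == pytest.approx(-cfg.sf_effect_size, rel=1e-9)
    for g in sf.index.difference([driver_sf]):
        s = np.polyfit(ages, np.log2(sf.loc[g].to_numpy()), 1)[0]
        assert abs(s) < 1e-9


def test_disease_prevalence_half_when_all_effects_zero():
    cfg = ag.SimulationConfig(
        n_individuals=4000, n_events=20, n_genes=10,
        disease_intercept=0.0, disease_age_effect=0.0,
        disease_gender_effect=0.0, disease_expr_effect=0.0,
        disease_effect=0.0, seed=8,
    )
    cohort = ag.simulate_cohort(cfg)
    psi, truth = ag.simulate_psi(cohort, cfg)
    gene, _, _ = ag.simulate_expression(cohort, cfg)
    d = ag.simulate_disease(cohort, psi, gene, cfg, truth)
    assert abs(d.mean() - 0.5) < 0.03


def test_disease_psi_component_association_detectable():
    # planted PSI effect: a 2x2 Fisher test at the component's median split
    # must see the association on one seeded draw
    cfg = ag.SimulationConfig(
        n_individuals=500, n_events=100, frac_age_assoc=0.2,
        disease_effect=2.0, seed=9,
    )
    cohort = ag.simulate_cohort(cfg)
    psi, truth = ag.simulate_psi(cohort, cfg)
    gene, _, _ = ag.simulate_expression(cohort, cfg)
    d = ag.simulate_disease(cohort, psi, gene, cfg, truth).to_numpy()
    from agesplice.simulate import _pc1_scores
    from agesplice.association import _impute_row_means

    comp = _pc1_scores(_impute_row_means(
        psi.values.loc[truth.events.is_age_assoc].to_numpy()))
    hi = comp > np.median(comp)
    table = [
        [int(((d == 1) & hi).sum()), int(((d == 1) & ~hi).sum())],
        [int(((d == 0) & hi).sum()), int(((d == 0) & ~hi).sum())],
    ]
    assert stats.fisher_exact(table).pvalue < 0.01
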