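"""Trend classes, IUPAC motif counting, enrichment and driver calls."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import agesplice as ag
from agesplice.drivers import _mechanism, rank_sum_test
from agesplice.motifs import IUPAC_CODES, count_occurrences
from agesplice.regions import DEFAULT_REGION_LENGTHS, REGION_NAMES, EventRegions


def _results_frame(rows):
    return pd.DataFrame(
        rows, columns=["tested", "significant", "direction", "p_value"],
        index=[f"e{i}" for i in range(len(rows))],
    )


def test_classify_trend_rules():
    res = _results_frame([
        (True, True, 1, 1e-6),    # up
        (True, True, -1, 1e-5),   # down
        (True, False, 1, 0.7),    # stable
        (True, False, 1, 0.1),    # buffer zone: no class
        (False, False, 0, np.nan),  # untested: no class
    ])
    trend = ag.classify_trend(res)
    assert trend.to_dict() == {"e0": "up", "e1": "down", "e2": "stable"}


def test_motif_count_examples_and_validation():
    assert count_occurrences("ACGTACGT", "ACGT") == 2
    assert count_occurrences("CTCTCT", "CT") == 3  # overlap semantics
    assert count_occurrences("ACAT", "YCAY") == 0
    assert count_occurrences("TCATACAC", "YCAY") == 1
    assert count_occurrences("ACNT", "ACGT") == 0  # N never matches
    with pytest.raises(ValueError, match="IUPAC"):
        count_occurrences("ACGT", "ACXT")
    with pytest.raises(ValueError):
        ag.MotifRecord("m", "SF", "")


def _naive_scan(seq, consensus):
    hits = 0
    m = len(consensus)
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in IUPAC_CODES[c] for j, c in enumerate(consensus)):
            hits += 1
    return hits


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGTN", min_size=0, max_size=120),
    st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6),
)
def test_motif_counting_matches_naive_scanner(seq, consensus):
    assert count_occurrences(seq, consensus) == _naive_scan(seq, consensus)


def test_count_motif_occurrences_per_region():
    seqs = {r: "A" * 20 for r in REGION_NAMES}
    seqs["cassette_exon"] = "ACGTACGTAA"
    ev = EventRegions("e1", seqs)
    counts = ag.count_motif_occurrences(ev, ag.MotifRecord("m", "SF", "ACGT"))
    assert counts["cassette_exon"] == 2
    assert all(counts[r] == 0 for r in REGION_NAMES if r != "cassette_exon")


def test_event_regions_validation():
    with pytest.raises(ValueError, match="regions must be exactly"):
        EventRegions("e1", {"cassette_exon": "ACGT"})
    bad = {r: "ACGT" for r in REGION_NAMES}
    bad["cassette_exon"] = "ACGU"
    with pytest.raises(ValueError, match="non-ACGTN"):
        EventRegions("e1", bad)


def _exact_ranksum_p(x, y):
    """Enumerate every assignment of the pooled values to the two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    m = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    extreme = 0
    total = comb(len(pooled), n1)
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - m) >= abs(u_obs - m) - 1e-12:
            extreme += 1
    return extreme / total


def test_rank_sum_exact_small_sample_values():
    p = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(_exact_ranksum_p([1, 2, 3], [4, 5, 6]), abs=1e-12)
    assert p == pytest.approx(2 / 20, abs=1e-12)  # 2 of the 20 assignments
    assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0  # identical distributions


def _toy_counts(rng, n_up=15, n_stable=20, n_down=15, boost=None):
    motifs = [ag.MotifRecord("mA", "SFA", "ACGT"), ag.MotifRecord("mB", "SFB", "GGA")]
    events, classes = [], {}
    rows = []
    i = 0
    for klass, n in (("up", n_up), ("stable", n_stable), ("down", n_down)):
        for _ in range(n):
            eid = f"e{i}"
            i += 1
            events.append(eid)
            classes[eid] = klass
            row = {}
            for m in motifs:
                for r in REGION_NAMES:
                    lam = 1.0
                    if boost and (m.motif_id, r, klass) == boost:
                        lam = 6.0
                    row[(m.motif_id, r)] = rng.poisson(lam)
            rows.append(row)
    counts = pd.DataFrame(rows, index=events)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                               names=["motif_id", "region"])
    return counts, pd.Series(classes), motifs


def test_enrichment_identical_distributions_never_significant():
    rng = np.random.default_rng(1)
    counts, classes, motifs = _toy_counts(rng)
    enr = ag.motif_enrichment_scan(counts, classes, motifs, fdr=0.1)
    assert not enr["enriched"].any()
    assert (enr["q_value"] >= enr["p_value"] - 1e-12).all()


def test_enrichment_recovers_planted_cell():
    rng = np.random.default_rng(2)
    boost = ("mA", "cassette_exon", "up")
    counts, classes, motifs = _toy_counts(rng, boost=boost)
    enr = ag.motif_enrichment_scan(counts, classes, motifs, fdr=0.1)
    top = enr.sort_values("p_value").iloc[0]
    assert (top.motif_id, top.region, top.contrast) == (
        "mA", "cassette_exon", "up-vs-stable"
    )
    assert top.enriched


def test_enrichment_empty_class_rejected():
    rng = np.random.default_rng(3)
    counts, classes, motifs = _toy_counts(rng, n_down=0)
    with pytest.raises(ValueError, match="empty"):
        ag.motif_enrichment_scan(counts, classes, motifs)


def test_identify_drivers_requires_sf_age_association(small_dataset):
    enr = pd.DataFrame(
        {
            "motif_id": ["mX"], "sf_gene": ["FLATSF"], "region": ["cassette_exon"],
            "contrast": ["up-vs-stable"], "p_value": [1e-5], "direction": [1],
            "q_value": [1e-4], "enriched": [True],
        }
    )
    cohort = small_dataset.cohort
    rng = np.random.default_rng(0)
    sf = pd.DataFrame(
        [rng.uniform(40, 60, len(cohort))], index=["FLATSF"],
        columns=cohort.sample_ids,
    )
    calls, untestable = ag.identify_drivers(enr, sf, cohort.table)
    assert calls == [] and untestable == []
    # SF absent from the matrix -> untestable, not an error
    calls, untestable = ag.identify_drivers(
        enr, sf.rename(index={"FLATSF": "OTHER"}), cohort.table
    )
    assert untestable == ["FLATSF"]
    # no enrichments -> empty call set
    calls, untestable = ag.identify_drivers(enr.iloc[:0], sf, cohort.table)
    assert calls == [] and untestable == []


def test_mechanism_notes():
    assert _mechanism("up-vs-stable", -0.01) == "repressor-down -> inclusion-up"
    assert _mechanism("up-vs-stable", 0.01) == "activator-up -> inclusion-up"
    assert _mechanism("down-vs-stable", -0.01) == "activator-down -> inclusion-down"
    assert _mechanism("down-vs-stable", 0.01) == "repressor-up -> inclusion-down"


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    from math import comb as C

    n = a + b + c + d
    row1, col1 = a + b, a + c
    def prob(x):
        return C(col1, x) * C(n - col1, row1 - x) / C(n, row1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def test_target_overlap_fisher_matches_enumeration_oracle():
    background = [f"g{i}" for i in range(20)]
    pipeline = set(background[:10])
    external = set(background[:8]) | {background[18]}
    odds, p = ag.target_overlap_test(pipeline, external, background)
    a = len(pipeline & external)
    b = len(pipeline - external)
    c = len(external - pipeline)
    d = 20 - a - b - c
    assert (a, b, c, d) == (8, 2, 1, 9)
    assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-12)
    assert odds == pytest.approx((a * d) / (b * c))


def test_target_overlap_degenerate_and_validation():
    bg = {"a", "b", "c"}
    odds, p = ag.target_overlap_test(bg, bg, bg)
    assert np.isinf(odds) and p == 1.0
    with pytest.raises(ValueError, match="background"):
        ag.target_overlap_test({"a"}, {"a"}, set())
    with pytest.raises(ValueError, match="subset"):
        ag.target_overlap_test({"zz"}, {"a"}, bg)


def test_target_overlap_type_one_rate():
    # independent random sets: p <= 0.05 in about 5% of seeds (discrete test
    # is conservative, so the band is one-sided below the nominal level)
    background = [f"g{i}" for i in range(60)]
    hits = 0
    n_seeds = 300
    for s in range(n_seeds):
        rng = np.random.default_rng(s)
        pipe = set(rng.choice(background, 20, replace=False))
        ext = set(rng.choice(background, 20, replace=False))
        hits += ag.target_overlap_test(pipe, ext, background)[1] <= 0.05
    assert hits / n_seeds <= 0.08


def test_region_lengths_defaults():
    assert set(DEFAULT_REGION_LENGTHS) == set(REGION_NAMES)
    assert DEFAULT_REGION_LENGTHS["cassette_exon"] == 100
    assert DEFAULT_REGION_LENGTHS["upstream_intron_3p"] == 200
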