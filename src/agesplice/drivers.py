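"""Upstream splicing-factor driver detection for age-associated exon skipping.

Cassette-exon events are split into three trend classes (inclusion up with
age, stable, down). For every RNA motif and each of the seven regions around
the exon, per-event occurrence counts in the up (or down) class are compared
with the stable background by a two-sided rank-sum test, BH-corrected across
the whole scan. A splicing factor is nominated as a driver when (i) its own
expression is age-associated (nominal p <= 0.05) and (ii) at least one of its
motifs is enriched (q <= 0.1, elevated in the changing class). The mechanism
note follows repressor/activator logic: e.g. a repressor whose expression
falls with age explains rising inclusion of the exons it binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .association import HiddenFactors, benjamini_hochberg, fit_age_model
from .modalities import log2_transform
from .motifs import MotifRecord, count_occurrences
from .regions import REGION_NAMES, EventRegions

CONTRASTS = ("up-vs-stable", "down-vs-stable")


def classify_trend(
    results: pd.DataFrame, stable_p_floor: float = 0.5
) -> pd.Series:
    """Assign events to trend classes: up / down (significant, by coefficient
    sign) or stable (tested, non-significant, nominal p >= ``stable_p_floor``).

    Tested events in the buffer zone (non-significant but p below the floor)
    belong to no class and are absent from the result.
    """
    classes = {}
    for event_id, row in results.iterrows():
        if not row["tested"]:
            continue
        if row["significant"]:
            classes[event_id] = "up" if row["direction"] > 0 else "down"
        elif row["p_value"] >= stable_p_floor:
            classes[event_id] = "stable"
    return pd.Series(classes, dtype=object, name="trend_class")


def count_motif_occurrences(
    regions: EventRegions, motif: MotifRecord
) -> dict[str, int]:
    """Overlapping IUPAC-degenerate match counts of one motif per region."""
    return {
        region: count_occurrences(regions[region], motif.consensus)
        for region in REGION_NAMES
    }


def count_matrix(
    regions: Mapping[str, EventRegions], motifs: Sequence[MotifRecord]
) -> pd.DataFrame:
    """Events x (motif, region) occurrence-count table."""
    cols = pd.MultiIndex.from_product(
        [[m.motif_id for m in motifs], list(REGION_NAMES)],
        names=["motif_id", "region"],
    )
    data = np.zeros((len(regions), len(cols)), dtype=int)
    event_ids = list(regions)
    for i, eid in enumerate(event_ids):
        j = 0
        for m in motifs:
            counts = count_motif_occurrences(regions[eid], m)
            for region in REGION_NAMES:
                data[i, j] = counts[region]
                j += 1
    return pd.DataFrame(data, index=pd.Index(event_ids, name="event_id"),
                        columns=cols)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value (exact for small
    tie-free samples, normal approximation with tie correction otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def motif_enrichment_scan(
    counts: pd.DataFrame,
    classes: pd.Series,
    motifs: Sequence[MotifRecord],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Rank-sum enrichment of every (motif, region) in up/down vs stable events.

    ``counts`` is the ``count_matrix`` output; ``classes`` maps event IDs to
    trend classes. Direction +1 means the changing class carries more motif
    occurrences than the stable background. BH correction spans the full scan
    (both contrasts, all motifs and regions).
    """
    classes = classes.reindex(counts.index).dropna()
    groups = {k: classes.index[classes == k] for k in ("up", "stable", "down")}
    if len(groups["stable"]) == 0:
        raise ValueError("stable class is empty; enrichment background undefined")
    rows = []
    for contrast in CONTRASTS:
        klass = contrast.split("-")[0]
        idx = groups[klass]
        if len(idx) == 0:
            raise ValueError(f"class {klass!r} is empty for contrast {contrast}")
        for m in motifs:
            for region in REGION_NAMES:
                x = counts.loc[idx, (m.motif_id, region)].to_numpy()
                bg = counts.loc[groups["stable"], (m.motif_id, region)].to_numpy()
                p = rank_sum_test(x, bg)
                direction = int(np.sign(np.median(x) - np.median(bg)))
                rows.append(
                    {
                        "motif_id": m.motif_id,
                        "sf_gene": m.sf_gene,
                        "region": region,
                        "contrast": contrast,
                        "p_value": p,
                        "direction": direction,
                        "n_class": len(x),
                        "n_stable": len(bg),
                    }
                )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["enriched"] = (out["q_value"] <= fdr) & (out["direction"] > 0)
    return out


@dataclass
class DriverCall:
    """A splicing factor nominated as an upstream driver."""

    sf_gene: str
    sf_beta_age: float
    sf_p_age: float
    enrichments: pd.DataFrame
    mechanism: str
    motif_ids: list[str] = field(default_factory=list)


def _mechanism(contrast: str, sf_slope: float) -> str:
    inclusion = "inclusion-up" if contrast.startswith("up") else "inclusion-down"
    sf_dir = "down" if sf_slope < 0 else "up"
    # an SF whose level moves against the inclusion change acts as a repressor
    repressor = (contrast.startswith("up")) == (sf_slope < 0)
    role = "repressor" if repressor else "activator"
    return f"{role}-{sf_dir} -> {inclusion}"


def identify_drivers(
    enrichments: pd.DataFrame,
    sf_expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    enrichment_fdr: float = 0.1,
    sf_p_threshold: float = 0.05,
    factors: Optional[HiddenFactors] = None,
    min_samples: int = 50,
) -> tuple[list[DriverCall], list[str]]:
    """Intersect motif enrichment with SF age-associated expression.

    Returns the driver calls plus the SF genes that had enriched motifs but
    were absent from the expression matrix (untestable, not an error).
    ``sf_expression`` is transcript-level TPM-like (rows SF genes); the age
    association is fitted on log2(x+1) with the same covariate structure as
    the splicing scan.
    """
    hits = enrichments[
        (enrichments["q_value"] <= enrichment_fdr) & (enrichments["direction"] > 0)
    ]
    calls: list[DriverCall] = []
    untestable: list[str] = []
    pheno = phenotypes
    log_sf = log2_transform(sf_expression)
    for sf_gene, sub in hits.groupby("sf_gene"):
        if sf_gene not in log_sf.index:
            untestable.append(sf_gene)
            continue
        row = log_sf.loc[sf_gene].reindex(pheno.index).to_numpy(dtype=float)
        fit = fit_age_model(
            row,
            pheno["age"].to_numpy(dtype=float),
            pheno["gender"].to_numpy(dtype=float),
            factors,
            min_samples=min_samples,
        )
        if not fit.tested or fit.p_age > sf_p_threshold:
            continue
        top = sub.sort_values("q_value").iloc[0]
        calls.append(
            DriverCall(
                sf_gene=sf_gene,
                sf_beta_age=fit.beta_age,
                sf_p_age=fit.p_age,
                enrichments=sub.reset_index(drop=True),
                mechanism=_mechanism(top["contrast"], fit.beta_age),
                motif_ids=sorted(sub["motif_id"].unique()),
            )
        )
    return calls, untestable


def target_overlap_test(
    pipeline_targets: Iterable[str],
    external_targets: Iterable[str],
    background: Iterable[str],
) -> tuple[float, float]:
    """Fisher exact test of pipeline-vs-external target overlap.

    Returns (odds ratio, two-sided p). A degenerate table with an empty
    off-diagonal yields an infinite odds ratio.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background gene set is empty")
    pipe = frozenset(pipeline_targets)
    ext = frozenset(external_targets)
    if not pipe <= bg or not ext <= bg:
        raise ValueError("target sets must be subsets of the background")
    a = len(pipe & ext)
    b = len(pipe - ext)
    c = len(ext - pipe)
    d = len(bg - pipe - ext)
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = res.statistic
    if not np.isfinite(odds) or np.isnan(odds):
        odds = np.inf
    return float(odds), float(res.pvalue)
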