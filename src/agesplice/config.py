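"""Simulation configuration: the stated synthetic world every stage is tested on.

The generator emulates a GTEx-like single-tissue cohort: donors with uniform
ages, Bernoulli(0.5) gender, bounded PSI values with logit-linear age trends,
shared hidden batch-like factors, gene-not-expressed missingness (the SUPPA
``-1`` sentinel), nested gene/transcript expression, motif-planted flanking
regions for trend-classified cassette exons, splicing-factor expression with
concordant age trends, and binary disease labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .motifs import MotifRecord
from .regions import REGION_NAMES

#: Degenerate consensuses for a small panel of well-known splicing factors.
#: The PTBP1-like pyrimidine motif is the default planted driver; the rest
#: act as decoys occurring at background rate everywhere.
DEFAULT_MOTIFS: tuple[MotifRecord, ...] = (
    MotifRecord("M_PTBP1", "PTBP1", "YCTCY"),
    MotifRecord("M_RBFOX1", "RBFOX1", "TGCATG"),
    MotifRecord("M_NOVA1", "NOVA1", "YCAY"),
    MotifRecord("M_SRSF1", "SRSF1", "GGAGGA"),
    MotifRecord("M_HNRNPA1", "HNRNPA1", "TAGGGW"),
    MotifRecord("M_QKI", "QKI", "ACTAAY"),
    MotifRecord("M_MBNL1", "MBNL1", "YGCY"),
    MotifRecord("M_CELF1", "CELF1", "GTGTG"),
)

TREND_CLASSES = ("up", "stable", "down")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort and its molecular matrices.

    Units: ``effect_size`` and ``noise_sd`` are on the logit(PSI) scale
    (``effect_size`` per year of age); ``expr_effect_size`` and expression
    noise are on the log2 scale per year. The default effect size, 0.016
    logit/year, gives a ~0.2 PSI shift across the default 20-70 year age
    range for an event centred at PSI 0.5.
    """

    n_individuals: int = 150
    age_range: tuple[float, float] = (20.0, 70.0)
    n_events: int = 500
    frac_age_assoc: float = 0.2
    effect_size: float = 0.016
    n_hidden_factors: int = 3
    factor_sd: float = 0.25
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    gene_dropout_rate: float = 0.0
    gender_effect_sd: float = 0.3
    n_genes: int = 100
    n_transcripts_per_gene: int = 2
    # expression generator
    expr_frac_age_assoc: float = 0.2
    expr_effect_size: float = 0.01
    expr_noise_sd: float = 0.3
    frac_isoform_switch: float = 0.1
    switch_effect_size: float = 0.02
    ratio_noise_sd: float = 0.2
    # regions / driver generator
    motif_set: tuple[MotifRecord, ...] = DEFAULT_MOTIFS
    planted_driver: Optional[tuple[str, str, str]] = (
        "M_PTBP1",
        "upstream_intron_3p",
        "up",
    )
    motif_planted_rate: float = 3.0
    motif_background_rate: float = 0.0
    region_lengths: Optional[dict[str, int]] = None
    sf_effect_size: float = 0.02
    sf_noise_sd: float = 0.2
    # disease generator (coefficients of the Bernoulli-logit disease model,
    # all on standardized covariates)
    disease_intercept: float = 0.0
    disease_age_effect: float = 0.5
    disease_gender_effect: float = 0.3
    disease_expr_effect: float = 0.5
    disease_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.n_individuals < 1:
            errs.append("n_individuals must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            errs.append("age_range must satisfy min < max")
        for name in ("n_events", "n_hidden_factors", "n_genes",
                     "n_transcripts_per_gene"):
            if getattr(self, name) < 1 and name != "n_hidden_factors":
                errs.append(f"{name} must be >= 1")
        if self.n_hidden_factors < 0:
            errs.append("n_hidden_factors must be >= 0")
        for name in ("frac_age_assoc", "expr_frac_age_assoc",
                     "frac_isoform_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must be in [0, 1]")
        for name in ("missing_rate", "gene_dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                errs.append(f"{name} must be in [0, 1)")
        for name in ("factor_sd", "noise_sd", "gender_effect_sd",
                     "expr_noise_sd", "ratio_noise_sd", "sf_noise_sd",
                     "motif_planted_rate", "motif_background_rate"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be >= 0")
        if self.planted_driver is not None:
            motif_id, region, trend = self.planted_driver
            if motif_id not in {m.motif_id for m in self.motif_set}:
                errs.append(f"planted_driver motif {motif_id!r} not in motif_set")
            if region not in REGION_NAMES:
                errs.append(
                    f"planted_driver region {region!r} unknown "
                    f"(expected one of {REGION_NAMES})"
                )
            if trend not in ("up", "down"):
                errs.append("planted_driver trend_class must be 'up' or 'down'")
        if self.region_lengths is not None:
            extra = set(self.region_lengths) - set(REGION_NAMES)
            if extra:
                errs.append(f"region_lengths has unknown regions {sorted(extra)}")
        if errs:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errs))

    @property
    def n_flagged_events(self) -> int:
        return int(round(self.frac_age_assoc * self.n_events))
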