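"""Synthetic GTEx-like single-tissue data with known ground truth.

The generator inverts the downstream models: PSI is logit-linear in age with
gender effects, shared hidden factors, and Gaussian logit-scale noise, mapped
through the inverse logit so every quantifiable value stays in [0, 1];
expression is log-normal with transcripts nested inside genes (gene = exact
sum of its transcripts); motif occurrences are planted in flanking regions of
trend-classified cassette exons; disease labels follow a Bernoulli-logit model
in age, gender, an expression component and a PSI component.

Identical configurations (including the seed) yield byte-identical outputs:
each stage draws from its own deterministic child stream of ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit used by callers/tests)

from .config import SimulationConfig
from .containers import SENTINEL, Cohort, GroundTruth, PsiMatrix
from .regions import DEFAULT_REGION_LENGTHS, REGION_NAMES, EventRegions
from .motifs import IUPAC_CODES

_STAGE_COHORT = 1
_STAGE_PSI = 2
_STAGE_EXPR = 3
_STAGE_REGIONS = 4
_STAGE_DISEASE = 5

_ACGT = np.array(list("ACGT"))


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _gene_names(config: SimulationConfig) -> list[str]:
    w = max(4, len(str(config.n_genes)))
    return [f"G{i:0{w}d}" for i in range(1, config.n_genes + 1)]


def _event_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Deterministic SUPPA-style exon-skipping IDs plus their gene names."""
    genes = _gene_names(config)
    ids, ev_genes = [], []
    for i in range(config.n_events):
        g = genes[i % config.n_genes]
        a = 10_000 * (i + 1)
        ids.append(f"{g};SE:chr1:{a}-{a + 200}:{a + 300}-{a + 500}:+")
        ev_genes.append(g)
    return ids, ev_genes


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw donors: ages uniform over ``age_range``, gender Bernoulli(0.5)."""
    rng = _rng(config, _STAGE_COHORT)
    n = config.n_individuals
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    genders = rng.integers(0, 2, size=n)
    w = max(4, len(str(n)))
    donors = [f"D{i:0{w}d}" for i in range(1, n + 1)]
    samples = [f"{d}-S1" for d in donors]
    table = pd.DataFrame(
        {"donor_id": donors, "age": ages, "gender": genders},
        index=pd.Index(samples, name="sample_id"),
    )
    return Cohort(table)


def _centered_age(cohort: Cohort, config: SimulationConfig) -> np.ndarray:
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    return cohort.ages.to_numpy(dtype=float) - mid


def simulate_psi(
    cohort: Cohort, config: SimulationConfig
) -> tuple[PsiMatrix, GroundTruth]:
    """PSI_ij = expit(alpha_i + beta_i age_j + gamma_i gender_j + sum_k lambda_ik f_kj + eps_ij)."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = _rng(config, _STAGE_PSI)
    n_ev, n = config.n_events, len(cohort)
    age_c = _centered_age(cohort, config)
    gender = cohort.genders.to_numpy(dtype=float)

    alpha = rng.normal(0.0, 1.0, size=n_ev)
    k_flag = config.n_flagged_events
    flagged_idx = rng.choice(n_ev, size=k_flag, replace=False) if k_flag else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=k_flag)
    beta = np.zeros(n_ev)
    beta[flagged_idx] = signs * config.effect_size
    gamma = rng.normal(0.0, config.gender_effect_sd, size=n_ev)
    k = config.n_hidden_factors
    loadings = rng.normal(0.0, config.factor_sd, size=(n_ev, k))
    factors = rng.normal(0.0, 1.0, size=(k, n))
    eps = rng.normal(0.0, config.noise_sd, size=(n_ev, n)) if config.noise_sd > 0 else 0.0

    lin = (
        alpha[:, None]
        + beta[:, None] * age_c[None, :]
        + gamma[:, None] * gender[None, :]
        + (loadings @ factors if k else 0.0)
        + eps
    )
    psi = expit(lin)

    if config.missing_rate > 0:
        psi[rng.random((n_ev, n)) < config.missing_rate] = SENTINEL
    event_ids, ev_genes = _event_ids(config)
    if config.gene_dropout_rate > 0:
        gene_arr = np.asarray(ev_genes)
        for g in _gene_names(config):
            drop = rng.random(n) < config.gene_dropout_rate
            if drop.any():
                psi[np.ix_(gene_arr == g, drop)] = SENTINEL

    values = pd.DataFrame(psi, index=pd.Index(event_ids, name="event_id"),
                          columns=cohort.sample_ids)
    trend = np.where(beta > 0, "up", np.where(beta < 0, "down", "stable"))
    truth = GroundTruth(
        events=pd.DataFrame(
            {
                "is_age_assoc": beta != 0.0,
                "beta_age": beta,
                "trend_class": trend,
                "gene": ev_genes,
            },
            index=values.index,
        ),
        factor_loadings=loadings,
        factors=factors,
    )
    return PsiMatrix(values), truth


def simulate_expression(
    cohort: Cohort, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Gene and transcript TPM-like matrices; gene row = exact sum of its transcripts.

    A configured fraction of genes carries a log2-linear age trend on the
    gene total (transcript ratios constant); a disjoint "isoform switch"
    fraction keeps the total flat while the transcript ratio drifts with age,
    so the signal exists only at transcript / ratio level.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = _rng(config, _STAGE_EXPR)
    n = len(cohort)
    genes = _gene_names(config)
    n_g, n_t = config.n_genes, config.n_transcripts_per_gene
    age_c = _centered_age(cohort, config)

    mu = rng.normal(5.0, 1.0, size=n_g)
    n_flag = int(round(config.expr_frac_age_assoc * n_g))
    perm = rng.permutation(n_g)
    flag_idx = perm[:n_flag]
    n_switch = int(round(config.frac_isoform_switch * n_g))
    switch_idx = perm[n_flag:n_flag + n_switch]
    b = np.zeros(n_g)
    b[flag_idx] = rng.choice([-1.0, 1.0], size=n_flag) * config.expr_effect_size
    k = config.n_hidden_factors
    loadings = rng.normal(0.0, config.factor_sd, size=(n_g, k))
    factors = rng.normal(0.0, 1.0, size=(k, n))
    eps = rng.normal(0.0, config.expr_noise_sd, size=(n_g, n)) if config.expr_noise_sd > 0 else 0.0
    log2_total = mu[:, None] + b[:, None] * age_c[None, :] + \
        (loadings @ factors if k else 0.0) + eps
    total = np.exp2(log2_total)

    theta = rng.normal(0.0, 1.0, size=(n_g, n_t))
    s = np.zeros((n_g, n_t))
    if n_t >= 2 and n_switch:
        sw_sign = rng.choice([-1.0, 1.0], size=n_switch)
        s[switch_idx, 0] = sw_sign * config.switch_effect_size
        s[switch_idx, 1] = -sw_sign * config.switch_effect_size
    ratio_eps = rng.normal(0.0, config.ratio_noise_sd, size=(n_g, n_t, n)) \
        if config.ratio_noise_sd > 0 else 0.0
    logits = theta[:, :, None] + s[:, :, None] * age_c[None, None, :] + ratio_eps
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)

    tx = total[:, None, :] * w                      # genes x transcripts x samples
    tx_names = [f"{g}.t{t + 1}" for g in genes for t in range(n_t)]
    tx_df = pd.DataFrame(
        tx.reshape(n_g * n_t, n),
        index=pd.Index(tx_names, name="transcript_id"),
        columns=cohort.sample_ids,
    )
    tx2gene = pd.Series([g for g in genes for _ in range(n_t)], index=tx_df.index)
    # gene value defined AS the column-wise sum of its transcripts -> exact
    gene_df = tx_df.groupby(tx2gene, sort=False).sum()
    gene_df.index.name = "gene_id"
    gene_df = gene_df.loc[genes]

    is_switch = np.zeros(n_g, bool)
    is_switch[switch_idx] = True
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"is_age_assoc": b != 0.0, "beta_age": b, "is_switch": is_switch},
            index=gene_df.index,
        ),
        transcripts=pd.DataFrame(
            {
                "gene": tx2gene,
                "ratio_trend": s.reshape(-1),
            },
            index=tx_df.index,
        ),
    )
    return gene_df, tx_df, truth


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _concretize(rng: np.random.Generator, consensus: str) -> np.ndarray:
    out = np.empty(len(consensus), dtype=np.int64)
    for i, c in enumerate(consensus):
        bases = IUPAC_CODES[c]
        out[i] = "ACGT".index(bases[rng.integers(0, len(bases))])
    return out


def simulate_regions_and_sf(
    cohort: Cohort,
    trend_classes: pd.Series,
    config: SimulationConfig,
) -> tuple[dict[str, EventRegions], pd.DataFrame]:
    """Region sequences for trend-classified cassette exons plus SF expression.

    Sequences are i.i.d. uniform nucleotides. Every motif may be inserted at
    a Poisson(``motif_background_rate``) rate in every region; the planted
    driver motif receives Poisson(``motif_planted_rate``) extra insertions in
    its configured region for events of its configured trend class. The
    driver's splicing factor gets a log2-linear age trend whose sign follows
    repressor logic (inclusion up with age => repressor expression down).
    """
    rng = _rng(config, _STAGE_REGIONS)
    lengths = dict(DEFAULT_REGION_LENGTHS)
    if config.region_lengths:
        lengths.update(config.region_lengths)
    driver = config.planted_driver
    regions: dict[str, EventRegions] = {}
    for event_id, klass in trend_classes.items():
        seqs: dict[str, str] = {}
        for region in REGION_NAMES:
            arr = _random_seq(rng, lengths[region])
            for motif in config.motif_set:
                rate = config.motif_background_rate
                if driver is not None and motif.motif_id == driver[0] \
                        and region == driver[1] and klass == driver[2]:
                    rate = rate + config.motif_planted_rate
                if rate <= 0:
                    continue
                n_ins = rng.poisson(rate)
                for _ in range(n_ins):
                    inst = _concretize(rng, motif.consensus)
                    if len(inst) > len(arr):
                        continue
                    pos = rng.integers(0, len(arr) - len(inst) + 1)
                    arr[pos:pos + len(inst)] = inst
            seqs[region] = "".join(_ACGT[arr])
        regions[event_id] = EventRegions(event_id, seqs)

    sf_genes = sorted({m.sf_gene for m in config.motif_set})
    age_c = _centered_age(cohort, config)
    n = len(cohort)
    driver_sf = None
    sf_slope = 0.0
    if driver is not None:
        motif_id, _, trend = driver
        driver_sf = next(m.sf_gene for m in config.motif_set if m.motif_id == motif_id)
        sf_slope = -config.sf_effect_size if trend == "up" else config.sf_effect_size
    rows = []
    for sf in sf_genes:
        mu = rng.normal(5.0, 1.0)
        slope = sf_slope if sf == driver_sf else 0.0
        eps = rng.normal(0.0, config.sf_noise_sd, size=n) if config.sf_noise_sd > 0 else 0.0
        rows.append(np.exp2(mu + slope * age_c + eps))
    sf_expr = pd.DataFrame(rows, index=pd.Index(sf_genes, name="sf_gene"),
                           columns=cohort.sample_ids)
    return regions, sf_expr


def _pc1_scores(matrix: np.ndarray) -> np.ndarray:
    """First principal-component sample scores with a deterministic sign."""
    x = matrix - matrix.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    score = s[0] * vt[0]
    if score[np.argmax(np.abs(score))] < 0:
        score = -score
    sd = score.std()
    return score / sd if sd > 0 else score


def simulate_disease(
    cohort: Cohort,
    psi: PsiMatrix,
    gene_expr: pd.DataFrame,
    config: SimulationConfig,
    truth: Optional[GroundTruth] = None,
) -> pd.Series:
    """Bernoulli disease labels driven by age, gender, an expression component
    and a PSI component.

    The PSI component is the first principal component of the age-associated
    event submatrix when the ground truth flags any (falling back to the full
    matrix), mirroring the downstream nested-model test which restricts
    splicing information to significant age-associated events.
    ``disease_effect = 0`` makes labels independent of PSI given the other
    covariates (the null world for likelihood-ratio calibration).
    """
    rng = _rng(config, _STAGE_DISEASE)
    ages = cohort.ages.to_numpy(dtype=float)
    sd = ages.std()
    z_age = (ages - ages.mean()) / sd if sd > 0 else np.zeros_like(ages)
    gender_c = cohort.genders.to_numpy(dtype=float) - 0.5

    ge = np.log2(gene_expr.to_numpy(dtype=float) + 1.0)
    ge_comp = _pc1_scores(ge)

    vals = psi.values.to_numpy(dtype=float).copy()
    if truth is not None and truth.events is not None and truth.events["is_age_assoc"].any():
        vals = vals[truth.events["is_age_assoc"].to_numpy()]
    mask = vals == SENTINEL
    if mask.any():
        row_mean = np.where(mask, np.nan, vals)
        means = np.nanmean(row_mean, axis=1)
        means = np.nan_to_num(means, nan=0.5)
        vals[mask] = np.take(means, np.where(mask)[0])
    psi_comp = _pc1_scores(vals)

    eta = (
        config.disease_intercept
        + config.disease_age_effect * z_age
        + config.disease_gender_effect * gender_c
        + config.disease_expr_effect * ge_comp
        + config.disease_effect * psi_comp
    )
    labels = (rng.random(len(cohort)) < expit(eta)).astype(int)
    return pd.Series(labels, index=cohort.sample_ids, name="disease")


@dataclass
class SyntheticDataset:
    """Everything one synthetic tissue provides, plus its ground truth."""

    config: SimulationConfig
    cohort: Cohort
    psi: PsiMatrix
    gene_expr: pd.DataFrame
    tx_expr: pd.DataFrame
    tx2gene: pd.Series
    regions: dict[str, EventRegions]
    sf_expr: pd.DataFrame
    truth: GroundTruth

    @property
    def phenotypes(self) -> pd.DataFrame:
        return self.cohort.table


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage under one configuration."""
    cohort = simulate_cohort(config)
    psi, truth = simulate_psi(cohort, config)
    gene_expr, tx_expr, expr_truth = simulate_expression(cohort, config)
    truth = truth.merged(expr_truth)
    tx2gene = expr_truth.transcripts["gene"]
    trend_classes = truth.events["trend_class"]
    regions, sf_expr = simulate_regions_and_sf(cohort, trend_classes, config)
    if config.planted_driver is not None:
        motif_id, region, trend = config.planted_driver
        sf_gene = next(m.sf_gene for m in config.motif_set if m.motif_id == motif_id)
        truth.driver = {
            "motif_id": motif_id,
            "region": region,
            "trend_class": trend,
            "sf_gene": sf_gene,
            "sf_slope_sign": -1 if trend == "up" else 1,
        }
    disease = simulate_disease(cohort, psi, gene_expr, config, truth)
    cohort.table["disease"] = disease
    truth.disease_coefs = {
        "intercept": config.disease_intercept,
        "age": config.disease_age_effect,
        "gender": config.disease_gender_effect,
        "expression": config.disease_expr_effect,
        "psi": config.disease_effect,
    }
    return SyntheticDataset(
        config=config,
        cohort=cohort,
        psi=psi,
        gene_expr=gene_expr,
        tx_expr=tx_expr,
        tx2gene=tx2gene,
        regions=regions,
        sf_expr=sf_expr,
        truth=truth,
    )
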