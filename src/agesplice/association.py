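"""Confounder-adjusted detection of age-associated molecular features.

Each feature (splicing event, gene, transcript or transcript ratio) is fitted
by ordinary least squares against donor age and gender plus hidden-factor
covariates estimated from the feature matrix itself (a principal-component
surrogate for PEER-style latent confounders). Features are called significant
only when both the Benjamini-Hochberg q-value passes the FDR threshold and
the empirical age-shuffling permutation p-value does too.

The permutation refits use the Frisch-Waugh-Lovell decomposition: the
response and the shuffled age vectors are residualized against the remaining
covariates once, after which every permutation's exact OLS t statistic for
the age coefficient is a vectorized dot product. The identity permutation
reproduces the full-design fit exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import SENTINEL

__all__ = [
    "HiddenFactors",
    "ModelFit",
    "RankDeficiencyError",
    "estimate_hidden_factors",
    "filter_age_correlated_factors",
    "fit_age_model",
    "benjamini_hochberg",
    "permutation_null",
    "call_significant",
    "scan_features",
]


class RankDeficiencyError(ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; offending column(s): {self.columns}"
        )


@dataclass
class HiddenFactors:
    """Sample-level latent confounders (factors x samples)."""

    values: pd.DataFrame
    age_corr_pvalues: Optional[pd.Series] = None

    @property
    def n_factors(self) -> int:
        return self.values.shape[0]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class ModelFit:
    """Per-feature OLS fit summary; ``tested=False`` marks skipped features."""

    tested: bool
    n_used: int
    reason: Optional[str] = None
    intercept: float = np.nan
    beta_age: float = np.nan
    se_age: float = np.nan
    t_age: float = np.nan
    p_age: float = np.nan
    beta_gender: float = np.nan
    factor_coefs: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    df_resid: int = 0
    mask: Optional[np.ndarray] = None


def _usable_mask(response: np.ndarray) -> np.ndarray:
    return np.isfinite(response) & (response != SENTINEL)


def _impute_row_means(matrix: np.ndarray) -> np.ndarray:
    """Replace sentinel/NaN cells with the row mean of the usable cells."""
    x = matrix.astype(float, copy=True)
    bad = ~np.isfinite(x) | (x == SENTINEL)
    if bad.any():
        masked = np.where(bad, np.nan, x)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(masked, axis=1)
        means = np.nan_to_num(means, nan=0.0)
        x[bad] = np.take(means, np.where(bad)[0])
    return x


def estimate_hidden_factors(
    feature_matrix: Union[pd.DataFrame, np.ndarray], n_factors: int = 20
) -> HiddenFactors:
    """Top sample-level singular vectors of the row-centered feature matrix.

    Sentinel cells are imputed with the feature's mean for estimation only.
    Row-centering puts the all-ones vector in the null space, so every factor
    has exactly zero mean across samples. Signs are fixed deterministically
    (largest-magnitude entry positive).
    """
    if isinstance(feature_matrix, pd.DataFrame):
        columns = feature_matrix.columns
        x = feature_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(feature_matrix, dtype=float)
        columns = pd.RangeIndex(x.shape[1])
    n_samples = x.shape[1]
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_samples < n_factors + 2:
        raise ValueError(
            f"need at least n_factors + 2 = {n_factors + 2} samples, got {n_samples}"
        )
    x = _impute_row_means(x)
    x -= x.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    fac = vt[:n_factors].copy()
    for row in fac:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    values = pd.DataFrame(
        fac, index=[f"F{i + 1}" for i in range(n_factors)], columns=columns
    )
    return HiddenFactors(values)


def estimate_confounders(
    feature_matrix: Union[pd.DataFrame, np.ndarray],
    ages: Union[pd.Series, np.ndarray],
    genders: Union[pd.Series, np.ndarray],
    n_factors: int = 20,
) -> HiddenFactors:
    """Surrogate-variable-style hidden factors for the age scan.

    The factor *loadings* (feature-space directions) are learned from the
    feature matrix residualized against age and gender, so genuine ageing
    signal cannot contaminate them; the factor *scores* are then obtained by
    projecting the raw (row-centered, sentinel-imputed) matrix onto those
    loadings, so each factor keeps its true sample pattern — including any
    chance in-sample correlation with age, which the downstream exclusion
    rule is meant to judge. Estimating scores directly from the raw SVD
    instead lets strong batch directions mix into age-correlated components;
    excluding those leaves shared confounding unadjusted and inflates the
    null, while scoring on residuals structurally hides the confounders'
    age-aligned part from the adjustment.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        columns = feature_matrix.columns
        x = feature_matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(feature_matrix, dtype=float)
        columns = pd.RangeIndex(x.shape[1])
    n_samples = x.shape[1]
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_samples < n_factors + 2:
        raise ValueError(
            f"need at least n_factors + 2 = {n_factors + 2} samples, got {n_samples}"
        )
    x = _impute_row_means(x)
    design = np.column_stack([
        np.ones(n_samples),
        np.asarray(ages, dtype=float),
        np.asarray(genders, dtype=float),
    ])
    q, _ = np.linalg.qr(design)
    resid = x - (x @ q) @ q.T
    u, _, _ = np.linalg.svd(resid, full_matrices=False)
    loadings = u[:, :n_factors]  # features x k, age-clean directions
    centered = x - x.mean(axis=1, keepdims=True)
    scores = loadings.T @ centered
    norms = np.linalg.norm(scores, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scores = scores / norms
    for row in scores:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    values = pd.DataFrame(
        scores, index=[f"F{i + 1}" for i in range(n_factors)], columns=columns
    )
    return HiddenFactors(values)


def filter_age_correlated_factors(
    factors: HiddenFactors, ages: Union[pd.Series, np.ndarray], alpha: float = 0.05
) -> HiddenFactors:
    """Drop factors whose Pearson correlation with age reaches p < ``alpha``.

    Removing them keeps genuine ageing signal out of the confounder
    adjustment; the retained factors carry their correlation p-values.
    """
    ages_arr = np.asarray(ages, dtype=float)
    if factors.n_factors == 0:
        return HiddenFactors(factors.values.copy(), pd.Series(dtype=float))
    if ages_arr.shape[0] != factors.values.shape[1]:
        raise ValueError("ages and factors are not aligned")
    if np.ptp(ages_arr) == 0:
        raise ValueError("age vector has zero variance; correlation undefined")
    pvals = {}
    for name, row in factors.values.iterrows():
        r = row.to_numpy(dtype=float)
        if np.ptp(r) == 0:
            pvals[name] = 1.0
            continue
        p = stats.pearsonr(r, ages_arr).pvalue
        pvals[name] = 1.0 if np.isnan(p) else float(p)
    keep = [name for name, p in pvals.items() if p >= alpha]
    return HiddenFactors(
        factors.values.loc[keep].copy(),
        pd.Series({k: pvals[k] for k in keep}, dtype=float),
    )


def _design(
    ages: np.ndarray, genders: np.ndarray, factors: Optional[np.ndarray]
) -> tuple[np.ndarray, list[str], bool]:
    # single-sex tissues (constant gender) lose the gender column instead of
    # producing a rank-deficient design
    has_gender = np.ptp(genders) > 0
    cols = [np.ones_like(ages), ages]
    names = ["intercept", "age"]
    if has_gender:
        cols.append(genders)
        names.append("gender")
    if factors is not None and factors.size:
        for i, row in enumerate(factors):
            cols.append(row)
            names.append(f"factor_{i + 1}")
    return np.column_stack(cols), names, has_gender


def _nuisance_columns(genders: np.ndarray, factors: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones_like(genders)]
    if np.ptp(genders) > 0:
        cols.append(genders)
    if factors is not None and factors.size:
        cols.extend(factors)
    return np.column_stack(cols)


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        raise RankDeficiencyError([names[j] for j in piv[rank:]])


def _coerce_factors(
    factors: Union[HiddenFactors, np.ndarray, None]
) -> Optional[np.ndarray]:
    if factors is None:
        return None
    if isinstance(factors, HiddenFactors):
        return factors.to_array()
    return np.atleast_2d(np.asarray(factors, dtype=float))


def fit_age_model(
    response: Union[pd.Series, np.ndarray],
    ages: Union[pd.Series, np.ndarray],
    genders: Union[pd.Series, np.ndarray],
    factors: Union[HiddenFactors, np.ndarray, None] = None,
    min_samples: int = 50,
) -> ModelFit:
    """OLS of one feature on age + gender + hidden factors.

    Cells equal to the ``-1`` sentinel (or non-finite) are excluded; the fit
    is skipped (``tested=False``) when fewer than ``min_samples`` usable
    samples remain or the usable response has zero variance. The age p-value
    is the two-sided t test on the age coefficient.
    """
    y_all = np.asarray(response, dtype=float)
    ages_all = np.asarray(ages, dtype=float)
    genders_all = np.asarray(genders, dtype=float)
    fac_all = _coerce_factors(factors)
    if not (y_all.shape == ages_all.shape == genders_all.shape):
        raise ValueError("response, ages and genders are not aligned")
    mask = _usable_mask(y_all)
    n_used = int(mask.sum())
    if n_used < min_samples:
        return ModelFit(tested=False, n_used=n_used, reason="insufficient_samples",
                        mask=mask)
    y = y_all[mask]
    if np.ptp(y) == 0:
        return ModelFit(tested=False, n_used=n_used, reason="zero_variance",
                        mask=mask)
    fac = fac_all[:, mask] if fac_all is not None else None
    x, names, has_gender = _design(ages_all[mask], genders_all[mask], fac)
    if n_used <= x.shape[1]:
        return ModelFit(tested=False, n_used=n_used, reason="insufficient_df",
                        mask=mask)
    _check_rank(x, names)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n_used - x.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    t_age = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1])
    p_age = float(2.0 * stats.t.sf(abs(t_age), df)) if np.isfinite(t_age) else 0.0
    n_fixed = 3 if has_gender else 2
    return ModelFit(
        tested=True,
        n_used=n_used,
        intercept=float(beta[0]),
        beta_age=float(beta[1]),
        se_age=float(se[1]),
        t_age=float(t_age),
        p_age=p_age,
        beta_gender=float(beta[2]) if has_gender else np.nan,
        factor_coefs=beta[n_fixed:].copy(),
        residuals=resid,
        df_resid=df,
        mask=mask,
    )


def benjamini_hochberg(p_values: Union[Sequence[float], np.ndarray]) -> np.ndarray:
    """Step-up BH adjusted q-values (capped at 1, monotone from the top)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _fwl_age_tstats(
    y: np.ndarray, age_rows: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, int]:
    """Exact OLS t statistics for the age coefficient, one per row of ``age_rows``.

    ``z`` is the remaining design (intercept, gender, factors). Residualizing
    both sides against ``z`` reduces each full fit to a univariate regression
    with df = n - ncol(z) - 1 (Frisch-Waugh-Lovell).
    """
    q, _ = np.linalg.qr(z)
    y_r = y - q @ (q.T @ y)
    a_r = age_rows - (age_rows @ q) @ q.T
    aa = np.einsum("ij,ij->i", a_r, a_r)
    num = a_r @ y_r
    yy = float(y_r @ y_r)
    df = y.shape[0] - z.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / aa
        rss = np.clip(yy - beta * num, 0.0, None)
        t = beta * np.sqrt(aa * df / np.where(rss > 0, rss, np.nan))
    t = np.where(aa <= 0, 0.0, t)
    t = np.where(np.isnan(t) & (aa > 0), np.inf, t)
    return t, df


def _permutation_stats(
    y: np.ndarray,
    age: np.ndarray,
    z: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """(perm_fraction, perm_pvalue) for one feature.

    ``perm_fraction`` is the share of shuffles whose age coefficient reaches
    nominal p <= ``alpha`` — a diagnostic that sits near ``alpha`` for any
    feature, because a shuffled regressor's t statistic is t-distributed
    regardless of the response. ``perm_pvalue`` is the empirical permutation
    p-value Pr(|t*| >= |t_obs|) (with the +1 small-sample correction), the
    quantity the significance call uses.
    """
    n = y.shape[0]
    t_obs, _ = _fwl_age_tstats(y, age[None, :], z)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = age[idx]
    t, df = _fwl_age_tstats(y, perms, z)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    frac = float(np.mean(np.abs(t) >= t_crit))
    pval = float((1.0 + np.sum(np.abs(t) >= np.abs(t_obs[0]))) / (n_perm + 1.0))
    return frac, pval


def permutation_null(
    response: Union[pd.Series, np.ndarray],
    ages: Union[pd.Series, np.ndarray],
    genders: Union[pd.Series, np.ndarray],
    factors: Union[HiddenFactors, np.ndarray, None],
    n_perm: int,
    seed: int,
    min_samples: int = 50,
    alpha: float = 0.05,
) -> float:
    """Fraction of age shuffles whose age coefficient reaches p <= ``alpha``.

    Ages are permuted across the usable samples while gender and factors stay
    fixed; each shuffle's model is refitted exactly (via FWL algebra).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fit = fit_age_model(response, ages, genders, factors, min_samples=min_samples)
    if not fit.tested:
        raise ValueError(
            f"permutation null undefined for untested feature (reason: {fit.reason})"
        )
    mask = fit.mask
    y = np.asarray(response, dtype=float)[mask]
    age = np.asarray(ages, dtype=float)[mask]
    fac = _coerce_factors(factors)
    z = _nuisance_columns(
        np.asarray(genders, dtype=float)[mask],
        fac[:, mask] if fac is not None else None,
    )
    rng = np.random.default_rng(seed)
    return _permutation_stats(y, age, z, n_perm, rng, alpha)[0]


def call_significant(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    perm_threshold: float = 0.05,
) -> pd.DataFrame:
    """Apply the dual criterion: q <= FDR threshold AND a quiet permutation null.

    The permutation side uses the empirical permutation p-value when present
    (column ``perm_pvalue``); tables carrying only the ``perm_fraction``
    diagnostic are vetoed on that instead.
    """
    out = results.copy()
    perm_col = "perm_pvalue" if "perm_pvalue" in out.columns else "perm_fraction"
    out["significant"] = (
        out["tested"]
        & (out["q_value"] <= fdr_threshold)
        & (out[perm_col] <= perm_threshold)
    )
    out["direction"] = np.sign(out["beta_age"]).fillna(0).astype(int)
    out.loc[~out["tested"], "direction"] = 0
    return out


def _event_seed(master_seed: int, feature_id: str) -> np.random.Generator:
    # a stable per-feature substream: results do not depend on iteration order
    h = zlib.crc32(str(feature_id).encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


def scan_features(
    feature_matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    n_factors: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    min_samples: int = 50,
    fdr_threshold: float = 0.05,
    perm_threshold: float = 0.05,
    use_factors: bool = True,
    factor_matrix: Optional[pd.DataFrame] = None,
    factor_alpha: float = 0.05,
    perm_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-feature scan: factor estimation, OLS, BH FDR, permutation null.

    ``feature_matrix`` is features x samples; ``phenotypes`` is indexed by
    sample ID with ``age`` and ``gender`` columns. Hidden factors are
    estimated from ``factor_matrix`` when given (e.g. the transcript matrix
    for the ratio scan) and from ``feature_matrix`` otherwise, then factors
    significantly correlated with age are excluded.
    """
    missing = feature_matrix.columns.difference(phenotypes.index)
    if len(missing):
        raise ValueError(f"samples missing from phenotype table: {list(missing)[:5]}")
    pheno = phenotypes.loc[feature_matrix.columns]
    ages = pheno["age"].to_numpy(dtype=float)
    genders = pheno["gender"].to_numpy(dtype=float)

    factors: Optional[HiddenFactors] = None
    if use_factors and n_factors > 0:
        src = factor_matrix if factor_matrix is not None else feature_matrix
        factors = estimate_confounders(src, ages, genders, n_factors=n_factors)
        factors = filter_age_correlated_factors(factors, ages, alpha=factor_alpha)
    fac_arr = factors.to_array() if factors is not None else None

    rows = []
    for feature_id, row in feature_matrix.iterrows():
        y_all = row.to_numpy(dtype=float)
        fit = fit_age_model(y_all, ages, genders, fac_arr, min_samples=min_samples)
        rec = {
            "tested": fit.tested,
            "n_used": fit.n_used,
            "beta_age": fit.beta_age,
            "se_age": fit.se_age,
            "p_value": fit.p_age,
            "perm_fraction": np.nan,
            "perm_pvalue": np.nan,
        }
        if fit.tested:
            mask = fit.mask
            z = _nuisance_columns(
                genders[mask], fac_arr[:, mask] if fac_arr is not None else None
            )
            rng = _event_seed(seed, feature_id)
            rec["perm_fraction"], rec["perm_pvalue"] = _permutation_stats(
                y_all[mask], ages[mask], z, n_perm, rng, perm_alpha
            )
        rows.append(rec)
    results = pd.DataFrame(rows, index=feature_matrix.index)
    results["q_value"] = np.nan
    tested = results["tested"].to_numpy()
    if tested.any():
        results.loc[tested, "q_value"] = benjamini_hochberg(
            results.loc[tested, "p_value"].to_numpy()
        )
    return call_significant(results, fdr_threshold, perm_threshold)
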