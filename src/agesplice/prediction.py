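"""Transcriptomic age models built on splicing / expression profiles.

Samples are first reduced by classical metric multidimensional scaling of
their Euclidean distances (numerically identical to principal-component
scores), then an L1-penalized (LASSO) linear model predicts age from the top
components. Accuracy is the Spearman correlation between each sample's mean
out-of-fold prediction over repeated 10-fold cross-validation and its true
age. Robust events are those repeatedly significant across permutation-seed
replicates of the detection pipeline; relative ages of independent samples
are reported as z-scores of predicted age against the training prediction
distribution, aggregated over many fitting rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV, LinearRegression, LogisticRegressionCV
from sklearn.model_selection import KFold, RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .association import _impute_row_means, scan_features
from .containers import PsiMatrix

DEFAULT_ALPHAS = np.logspace(-3.0, 1.0, 9)


class FeatureAlignmentError(ValueError):
    """Requested features are absent from a matrix."""


@dataclass
class ReducedFeatures:
    """Sample x component scores from classical metric MDS."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _as_matrix(profile: Union[pd.DataFrame, PsiMatrix]) -> pd.DataFrame:
    return profile.values if isinstance(profile, PsiMatrix) else profile


def mds_reduce(
    profile_matrix: Union[pd.DataFrame, PsiMatrix], n_components: int
) -> ReducedFeatures:
    """Classical metric MDS of samples on Euclidean distances.

    Sentinel cells are imputed with the feature mean. Implemented by
    eigendecomposition of the double-centered squared-distance Gram matrix;
    the resulting coordinates equal principal-component scores of the
    feature-centered sample matrix up to per-axis sign (fixed here so the
    largest-magnitude coordinate of each axis is positive).
    """
    mat = _as_matrix(profile_matrix)
    x = _impute_row_means(mat.to_numpy(dtype=float)).T  # samples x features
    n = x.shape[0]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components >= n:
        raise ValueError(
            f"n_components={n_components} must be smaller than n_samples={n}"
        )
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * j @ d2 @ j
    gram = 0.5 * (gram + gram.T)
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1][:n_components]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    scores = pd.DataFrame(
        coords,
        index=mat.columns,
        columns=[f"C{i + 1}" for i in range(n_components)],
    )
    return ReducedFeatures(scores, lam)


def fit_lasso(x: np.ndarray, y: np.ndarray, alpha: float):
    """L1 fit; alpha = 0 falls back to exact ordinary least squares."""
    if alpha == 0:
        return LinearRegression().fit(x, y)
    return Lasso(alpha=alpha, max_iter=50_000).fit(x, y)


def _scores(features: Union[ReducedFeatures, pd.DataFrame]) -> pd.DataFrame:
    return features.scores if isinstance(features, ReducedFeatures) else features


@dataclass
class CVPrediction:
    accuracy: float
    predictions: pd.Series  # mean out-of-fold predicted age per sample


def cv_age_prediction(
    features: Union[ReducedFeatures, pd.DataFrame],
    ages: Union[pd.Series, np.ndarray],
    n_repeats: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    alphas: Optional[np.ndarray] = None,
    inner_folds: int = 5,
) -> CVPrediction:
    """Repeated k-fold LASSO age prediction scored by Spearman correlation.

    The penalty is tuned by inner cross-validation within every training
    fold; each sample's prediction is the mean of its out-of-fold predictions
    across repeats.
    """
    x_df = _scores(features)
    y = np.asarray(ages, dtype=float)
    if len(x_df) != len(y):
        raise ValueError("features and ages are not aligned")
    if np.ptp(y) == 0:
        raise ValueError("ages are constant; Spearman accuracy undefined")
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    alphas = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas, float)
    x = x_df.to_numpy(dtype=float)
    rep_states = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31 - 1)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for r in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rep_states[r]))
        for train, test in kf.split(x):
            model = make_pipeline(
                StandardScaler(),
                LassoCV(alphas=alphas, cv=inner_folds, max_iter=50_000),
            )
            model.fit(x[train], y[train])
            pred_sum[test] += model.predict(x[test])
            pred_cnt[test] += 1.0
    mean_pred = pred_sum / pred_cnt
    rho = stats.spearmanr(mean_pred, y).statistic
    return CVPrediction(float(rho), pd.Series(mean_pred, index=x_df.index))


def old_young_classification(
    features: Union[ReducedFeatures, pd.DataFrame],
    ages: Union[pd.Series, np.ndarray],
    quantile: float = 0.25,
    n_repeats: int = 100,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Old-vs-young accuracy of an L1 classifier on the age-extreme quantiles.

    The oldest and youngest ``quantile`` fractions form the two classes
    (``quantile=0.5`` uses every sample via a median split); accuracy is the
    mean out-of-fold correctness over repeated stratified cross-validation.
    """
    x_df = _scores(features)
    y_age = np.asarray(ages, dtype=float)
    n = len(y_age)
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    k = int(np.floor(quantile * n))
    if k < 8:
        raise ValueError(f"need >= 8 samples per class, got {k}")
    order = np.argsort(y_age, kind="mergesort")
    young, old = order[:k], order[-k:]
    idx = np.concatenate([young, old])
    labels = np.concatenate([np.zeros(k, int), np.ones(k, int)])
    x = x_df.to_numpy(dtype=float)[idx]
    folds = min(n_folds, k)
    rskf = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=n_repeats, random_state=seed % (2**31 - 1)
    )
    correct = np.zeros(2 * k)
    count = np.zeros(2 * k)
    import warnings

    for train, test in rskf.split(x, labels):
        model = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=np.logspace(-2, 2, 5), penalty="l1", solver="liblinear",
                cv=3, max_iter=5_000,
            ),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(x[train], labels[train])
            correct[test] += model.predict(x[test]) == labels[test]
        count[test] += 1.0
    return float(np.mean(correct / count))


def select_robust_events(
    psi: Union[pd.DataFrame, PsiMatrix],
    phenotypes: pd.DataFrame,
    n_runs: int = 10,
    min_detections: int = 8,
    seed: int = 0,
    **scan_kwargs,
) -> list[str]:
    """Events significant in >= ``min_detections`` of ``n_runs`` pipeline runs.

    The detection pipeline is deterministic except for the permutation null,
    so runs differ only by their permutation master seed; events that keep
    reappearing across seeds are robust to that stochasticity.
    """
    if min_detections > n_runs:
        raise ValueError("min_detections cannot exceed n_runs")
    if min_detections < 1 or n_runs < 1:
        raise ValueError("n_runs and min_detections must be >= 1")
    mat = _as_matrix(psi)
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    counts = pd.Series(0, index=mat.index, dtype=int)
    for r in range(n_runs):
        res = scan_features(mat, phenotypes, seed=int(run_seeds[r]), **scan_kwargs)
        counts += res["significant"].astype(int)
    return list(counts.index[counts >= min_detections])


@dataclass
class AgeModel:
    """A fitted, serializable splicing age clock.

    Holds the L1 coefficients over MDS components, the chosen penalty, the
    feature pipeline (event list, per-event imputation means, component
    loadings) and the training predicted-age distribution used for z-scoring.
    """

    event_ids: list[str]
    event_means: np.ndarray         # imputation means, one per event
    component_loadings: np.ndarray  # events x components (maps profile -> scores)
    feature_means: np.ndarray       # per-component centering of the scores
    feature_scales: np.ndarray
    coefficients: np.ndarray
    intercept: float
    penalty: float
    train_predictions: np.ndarray

    def predict(self, psi: Union[pd.DataFrame, PsiMatrix]) -> pd.Series:
        mat = _as_matrix(psi)
        missing = [e for e in self.event_ids if e not in mat.index]
        if missing:
            raise FeatureAlignmentError(
                f"model events missing from matrix: {missing[:10]}"
            )
        x = mat.loc[self.event_ids].to_numpy(dtype=float).copy()
        bad = ~np.isfinite(x) | (x == -1.0)
        x[bad] = np.take(self.event_means, np.where(bad)[0])
        scores = (x - self.event_means[:, None]).T @ self.component_loadings
        scaled = (scores - self.feature_means) / self.feature_scales
        pred = scaled @ self.coefficients + self.intercept
        return pd.Series(pred, index=mat.columns, name="predicted_age")

    def zscore(self, psi: Union[pd.DataFrame, PsiMatrix]) -> pd.Series:
        mu = self.train_predictions.mean()
        sd = self.train_predictions.std()
        if sd <= 0:
            raise ValueError("training prediction distribution has zero spread")
        return (self.predict(psi) - mu) / sd

    def to_dict(self) -> dict:
        return {
            "event_ids": list(self.event_ids),
            "event_means": self.event_means.tolist(),
            "component_loadings": self.component_loadings.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "penalty": float(self.penalty),
            "train_predictions": self.train_predictions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeModel":
        return cls(
            event_ids=list(d["event_ids"]),
            event_means=np.asarray(d["event_means"], float),
            component_loadings=np.asarray(d["component_loadings"], float),
            feature_means=np.asarray(d["feature_means"], float),
            feature_scales=np.asarray(d["feature_scales"], float),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            penalty=float(d["penalty"]),
            train_predictions=np.asarray(d["train_predictions"], float),
        )


def build_age_model(
    psi: Union[pd.DataFrame, PsiMatrix],
    ages: Union[pd.Series, np.ndarray],
    n_components: int = 30,
    seed: int = 0,
    alphas: Optional[np.ndarray] = None,
    inner_folds: int = 5,
) -> AgeModel:
    """Fit the final age clock on the full training cohort.

    The MDS map is expressed as component loadings over (imputed, centered)
    event rows so the same reduction can be applied to new samples.
    """
    mat = _as_matrix(psi)
    y = np.asarray(ages, dtype=float)
    x_imp = _impute_row_means(mat.to_numpy(dtype=float))
    event_means = x_imp.mean(axis=1)
    centered = (x_imp - event_means[:, None]).T  # samples x events
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, (s > 1e-12).sum())
    loadings = vt[:k].T  # events x components
    for c in range(k):
        col = centered @ loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = centered @ loadings
    f_means = scores.mean(axis=0)
    f_scales = scores.std(axis=0)
    f_scales[f_scales == 0] = 1.0
    scaled = (scores - f_means) / f_scales
    alphas = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas, float)
    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed % (2**31 - 1))
    lasso = LassoCV(alphas=alphas, cv=cv, max_iter=50_000).fit(scaled, y)
    return AgeModel(
        event_ids=list(mat.index),
        event_means=event_means,
        component_loadings=loadings,
        feature_means=f_means,
        feature_scales=f_scales,
        coefficients=lasso.coef_,
        intercept=float(lasso.intercept_),
        penalty=float(lasso.alpha_),
        train_predictions=lasso.predict(scaled),
    )


@dataclass
class RelativeAgeReport:
    """Per-round z-scores of predicted test-sample ages, plus pair orderings."""

    zscores: pd.DataFrame           # rounds x test samples
    train_zscores: pd.DataFrame     # rounds x training samples
    comparisons: Optional[pd.DataFrame] = None


def compare_pairs(
    zscores: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Paired Wilcoxon ordering of (sample_a, sample_b) z-scores across rounds.

    The ordering call is the sign of the median z difference: positive means
    sample_a is predicted older.
    """
    rows = []
    for a, b in pairs:
        diff = (zscores[a] - zscores[b]).dropna().to_numpy()
        if diff.size == 0:
            raise ValueError(f"no valid rounds for pair ({a}, {b})")
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff).pvalue)
        med = float(np.median(diff))
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "median_z_diff": med,
                "wilcoxon_p": p,
                "call": "a_older" if med > 0 else ("b_older" if med < 0 else "tie"),
            }
        )
    return pd.DataFrame(rows)


def relative_age_zscores(
    train_psi: Union[pd.DataFrame, PsiMatrix],
    train_ages: Union[pd.Series, np.ndarray],
    test_psi: Union[pd.DataFrame, PsiMatrix],
    robust_events: Iterable[str],
    n_rounds: int = 100,
    seed: int = 0,
    alphas: Optional[np.ndarray] = None,
    inner_folds: int = 5,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> RelativeAgeReport:
    """Relative ages of independent samples from a robust-event LASSO model.

    Each round resamples the training cohort (bootstrap), tunes the penalty
    by randomized inner CV, predicts every test sample, and z-scores the
    predictions against that round's training prediction distribution.
    """
    events = list(robust_events)
    if not events:
        raise ValueError("robust_events is empty")
    train = _as_matrix(train_psi)
    test = _as_matrix(test_psi)
    missing = [e for e in events if e not in test.index]
    if missing:
        raise FeatureAlignmentError(
            f"robust events missing from test matrix: {missing[:10]}"
        )
    missing_tr = [e for e in events if e not in train.index]
    if missing_tr:
        raise FeatureAlignmentError(
            f"robust events missing from training matrix: {missing_tr[:10]}"
        )
    y = np.asarray(train_ages, dtype=float)
    alphas = DEFAULT_ALPHAS if alphas is None else np.asarray(alphas, float)

    tr = train.loc[events].to_numpy(dtype=float)
    te = test.loc[events].to_numpy(dtype=float)
    tr_imp = _impute_row_means(tr)
    row_means = tr_imp.mean(axis=1)
    te = te.copy()
    bad = ~np.isfinite(te) | (te == -1.0)
    te[bad] = np.take(row_means, np.where(bad)[0])
    x_train, x_test = tr_imp.T, te.T
    n_train = x_train.shape[0]

    round_states = np.random.SeedSequence(seed).generate_state(n_rounds) % (2**31 - 1)
    z_test = np.full((n_rounds, x_test.shape[0]), np.nan)
    z_train = np.full((n_rounds, n_train), np.nan)
    for r in range(n_rounds):
        rng = np.random.default_rng(int(round_states[r]))
        boot = rng.integers(0, n_train, size=n_train)
        cv = KFold(n_splits=inner_folds, shuffle=True,
                   random_state=int(round_states[r]))
        model = make_pipeline(
            StandardScaler(),
            LassoCV(alphas=alphas, cv=cv, max_iter=50_000),
        )
        model.fit(x_train[boot], y[boot])
        pred_train = model.predict(x_train)
        mu, sd = float(pred_train.mean()), float(pred_train.std())
        if sd <= 0:
            continue  # fully-shrunk round carries no ordering information
        z_test[r] = (model.predict(x_test) - mu) / sd
        z_train[r] = (pred_train - mu) / sd
    if np.isnan(z_test).all():
        raise ValueError("every fitting round collapsed to a constant model")
    zs = pd.DataFrame(z_test, columns=test.columns,
                      index=pd.RangeIndex(n_rounds, name="round"))
    zt = pd.DataFrame(z_train, columns=train.columns,
                      index=pd.RangeIndex(n_rounds, name="round"))
    comparisons = compare_pairs(zs, pairs) if pairs else None
    return RelativeAgeReport(zs, zt, comparisons)
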