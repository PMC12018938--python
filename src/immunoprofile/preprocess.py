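"""Five-step marker normalization.

Fixed order: (1) deselect markers highly Spearman-correlated with others,
(2) log10-transform flagged markers, (3) impute missing values by chained
L1-penalized regression, (4) remove the linear effect of days since
diagnosis, (5) z-score each marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold

from .simulate import Cohort

__all__ = [
    "ResidualizationModel",
    "NormalizedMatrix",
    "deselect_correlated",
    "log_transform",
    "impute_missing",
    "residualize_days",
    "standardize",
    "normalize_markers",
]

#: Fixed small penalty grid for the chained-Lasso imputer's internal CV;
#: the near-zero entry lets the CV fall back to an effectively
#: unpenalized fit when a marker is (close to) an exact linear function
#: of the others.
LASSO_ALPHA_GRID = (1e-8, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


class GridLassoCV(BaseEstimator, RegressorMixin):
    """Lasso with the penalty chosen by k-fold CV over a fixed grid.

    MSE ties break toward the smallest penalty (an exact linear dependence
    is then reproduced essentially unpenalized); if every penalized fit
    fails, falls back to plain OLS with a warning.
    """

    def __init__(self, alphas=LASSO_ALPHA_GRID, cv=3, max_iter=5000,
                 random_state=0):
        self.alphas = alphas
        self.cv = cv
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        kf = KFold(n_splits=min(self.cv, max(2, n // 2)), shuffle=True,
                   random_state=self.random_state)
        splits = list(kf.split(X))
        mse = np.full(len(self.alphas), np.inf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, a in enumerate(self.alphas):
                errs = []
                try:
                    for tr, te in splits:
                        m = Lasso(alpha=a, max_iter=self.max_iter)
                        m.fit(X[tr], y[tr])
                        errs.append(np.mean((m.predict(X[te]) - y[te]) ** 2))
                    mse[i] = float(np.mean(errs))
                except Exception:
                    continue
            if not np.isfinite(mse).any():
                warnings.warn("penalty selection failed; falling back to OLS")
                self.model_ = LinearRegression().fit(X, y)
                self.alpha_ = 0.0
                return self
            best = mse.min()
            tied = np.isfinite(mse) & (mse <= best * (1 + 1e-9) + 1e-15)
            self.alpha_ = float(min(np.asarray(self.alphas)[tied]))
            self.model_ = Lasso(alpha=self.alpha_, max_iter=self.max_iter)
            self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


@dataclass
class ResidualizationModel:
    """Per-marker (alpha, beta) from regressing marker on days since diagnosis."""

    intercepts: pd.Series
    slopes: pd.Series


@dataclass
class NormalizedMatrix:
    """Complete participants x markers matrix with column mean 0 and SD 1."""

    values: pd.DataFrame
    dropped: list = field(default_factory=list)
    imputation_mask: pd.DataFrame | None = None
    residualization: ResidualizationModel | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("normalized matrix must be complete")

    @property
    def marker_ids(self) -> list:
        return list(self.values.columns)


def _pairwise_spearman(df: pd.DataFrame) -> np.ndarray:
    """|rho| matrix on pairwise-complete observations."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = df.corr(method="spearman", min_periods=3).to_numpy()
    np.fill_diagonal(rho, 0.0)
    return np.abs(np.nan_to_num(rho))


def deselect_correlated(cohort: Cohort, threshold: float = 0.95):
    """Iteratively drop one member of each |Spearman rho| > threshold pair.

    Greedy rule: of the offending pair, drop the marker with the larger mean
    absolute correlation to all remaining markers (ties to earlier column
    order). Returns the reduced cohort and a provenance list of
    ``(dropped, partner, rho)`` tuples.
    """
    df = cohort.markers.copy()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    if (df.std(ddof=1) == 0).all():
        raise ValueError("all markers constant")
    dropped: list[tuple[str, str, float]] = []
    while True:
        a = _pairwise_spearman(df)
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= threshold:
            break
        mean_abs = a.mean(axis=0) * a.shape[0] / (a.shape[0] - 1)
        victim, partner = (i, j) if mean_abs[i] >= mean_abs[j] else (j, i)
        if mean_abs[i] == mean_abs[j]:
            victim, partner = min(i, j), max(i, j)
        dropped.append((df.columns[victim], df.columns[partner], float(a[i, j])))
        df = df.drop(columns=df.columns[victim])
    reduced = Cohort(
        cohort.metadata,
        df,
        cohort.marker_meta.loc[df.columns],
        None if cohort.responses is None
        else cohort.responses[[c for c in cohort.responses.columns if c in df.columns]],
        cohort.config,
    )
    return reduced, dropped


def log_transform(cohort: Cohort) -> Cohort:
    """log10-transform markers flagged ``log_transform`` in the metadata.

    Nonpositive values are floored at half the smallest positive observed
    value of that marker before taking logs; unflagged markers pass through.
    """
    df = cohort.markers.copy()
    for mk in df.columns:
        if not cohort.marker_meta.loc[mk, "log_transform"]:
            continue
        col = df[mk]
        pos = col[col > 0]
        if pos.empty:
            raise ValueError(f"marker {mk} flagged for log has no positive values")
        floor = pos.min() / 2.0
        df[mk] = np.log10(col.clip(lower=floor))
    return Cohort(cohort.metadata, df, cohort.marker_meta, cohort.responses,
                  cohort.config)


def impute_missing(cohort: Cohort, iterations: int = 10, seed: int = 0):
    """Chained-equations imputation with L1-penalized linear regressions.

    Missing cells start at column medians; markers are cycled in ascending
    order of missingness, each incomplete marker regressed on all others
    with a Lasso whose penalty is chosen by internal cross-validation over a
    fixed small grid. Observed cells are never altered. Every marker must be
    at least 50% observed.
    """
    df = cohort.markers
    frac_missing = df.isna().mean()
    if (frac_missing > 0.5).any():
        bad = list(frac_missing[frac_missing > 0.5].index)
        raise ValueError(f"markers with >50% missing cannot be imputed: {bad}")
    mask = df.isna()
    if not mask.to_numpy().any():
        return cohort, mask
    est = GridLassoCV(alphas=LASSO_ALPHA_GRID, cv=3, max_iter=5000,
                      random_state=seed % (2**31 - 1))
    imputer = IterativeImputer(
        estimator=est,
        max_iter=iterations,
        initial_strategy="median",
        imputation_order="ascending",
        sample_posterior=False,
        random_state=seed,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filled = imputer.fit_transform(df.to_numpy())
    out = pd.DataFrame(filled, index=df.index, columns=df.columns)
    out = out.where(mask, df)  # paranoia: observed cells verbatim
    imputed = Cohort(cohort.metadata, out, cohort.marker_meta, cohort.responses,
                     cohort.config)
    return imputed, mask


def residualize_days(cohort: Cohort):
    """Remove the days-since-diagnosis trend: y <- y - beta * days.

    Per marker, OLS of y on days (pooled over all participants); the
    intercept is retained, only the slope term is subtracted.
    """
    days = cohort.metadata["days_since_dx"].to_numpy(dtype=float)
    if np.var(days) == 0:
        raise ValueError("days since diagnosis has zero variance")
    x = days - days.mean()
    df = cohort.markers.copy()
    alphas, betas = {}, {}
    for mk in df.columns:
        y = df[mk].to_numpy(dtype=float)
        beta = float(np.dot(x, y - y.mean()) / np.dot(x, x))
        alpha = float(y.mean() - beta * days.mean())
        df[mk] = y - beta * days
        alphas[mk], betas[mk] = alpha, beta
    model = ResidualizationModel(pd.Series(alphas), pd.Series(betas))
    return (
        Cohort(cohort.metadata, df, cohort.marker_meta, cohort.responses,
               cohort.config),
        model,
    )


def standardize(cohort: Cohort) -> NormalizedMatrix:
    """z-score each marker column (sample SD, n-1 denominator)."""
    df = cohort.markers
    if df.isna().to_numpy().any():
        raise ValueError("standardize requires complete data")
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant columns: {list(sd[sd == 0].index)}")
    return NormalizedMatrix((df - df.mean()) / sd)


def normalize_markers(
    cohort: Cohort,
    deselect_threshold: float = 0.95,
    impute_iterations: int = 10,
    seed: int = 0,
) -> NormalizedMatrix:
    """Run the full pipeline: deselect -> log -> impute -> residualize -> z-score."""
    reduced, dropped = deselect_correlated(cohort, deselect_threshold)
    logged = log_transform(reduced)
    imputed, mask = impute_missing(logged, impute_iterations, seed)
    resid, model = residualize_days(imputed)
    out = standardize(resid)
    out.dropped = dropped
    out.imputation_mask = mask
    out.residualization = model
    return out
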