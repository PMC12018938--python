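"""Descriptive group tests and covariate-adjusted per-marker comparisons.

Per-marker machinery: response rates compared by Firth logistic regression
and magnitudes by log-linear (OLS on log-magnitude) regression, both
adjusted for the confounders (severity, age, sex, region, smoking, days
since diagnosis). Severity-stratified HIV effects come from linear
contrasts of a model with an HIV x severity interaction. q-values are
Benjamini-Hochberg within each assay family; a comparison is flagged
significant when p <= 0.05 and q <= 0.2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .config import SEVERITIES
from .firth import FirthLogit
from .simulate import Cohort

__all__ = [
    "chi_square_test",
    "welch_t_test",
    "bh_adjust",
    "loglinear_gmr_fit",
    "MarkerComparison",
    "MarkerComparisonResults",
]

DEFAULT_COVARIATES = ("age", "sex_male", "region_us", "smoking", "days_since_dx")


def chi_square_test(table, yates: bool = False):
    """Pearson chi-square test of independence on an r x c count table.

    With ``yates`` and a 2x2 table, the |O - E| - 0.5 continuity correction
    is applied, floored at zero. Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    correction = bool(yates) and t.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return float(chi2), int(df), float(p)


def welch_t_test(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sided Welch t-test from summary statistics.

    Unequal-variance t with Satterthwaite degrees of freedom; returns
    (t, df, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(p):
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def loglinear_gmr_fit(log_y, X, alpha: float = 0.05) -> pd.DataFrame:
    """OLS on log-magnitudes; coefficients exponentiated to geometric mean
    ratios with t-based confidence intervals."""
    res = sm.OLS(np.asarray(log_y, dtype=float), np.asarray(X, dtype=float)).fit()
    ci = res.conf_int(alpha)
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{i}" for i in range(res.params.size)])
    return pd.DataFrame(
        {
            "gmr": np.exp(res.params),
            "ci_lower": np.exp(ci[:, 0]),
            "ci_upper": np.exp(ci[:, 1]),
            "p": res.pvalues,
        },
        index=names,
    )


def _interaction_design(meta: pd.DataFrame, covars: pd.DataFrame):
    """Design with intercept, HIV, severity dummies, HIV x severity, covariates.

    Severity levels absent from the data are dropped from the design.
    """
    hiv = (meta["hiv_status"] == "PLWH").astype(float).to_numpy()
    cols = {"const": np.ones(len(meta)), "hiv": hiv}
    present = [s for s in SEVERITIES[1:] if (meta["severity"] == s).any()]
    for s in present:
        d = (meta["severity"] == s).astype(float).to_numpy()
        cols[f"sev_{s}"] = d
        cols[f"hiv:{s}"] = hiv * d
    for c in covars.columns:
        cols[c] = covars[c].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.index), present


def _stratum_contrast(names: list[str], stratum: str) -> np.ndarray:
    c = np.zeros(len(names))
    c[names.index("hiv")] = 1.0
    key = f"hiv:{stratum}"
    if key in names:
        c[names.index(key)] = 1.0
    return c


class MarkerComparison:
    """Per-marker, per-stratum comparison of PLWH vs PWOH.

    Parameters
    ----------
    cohort : Cohort
        Marker magnitudes (log-transformed internally where flagged) plus
        optional positivity calls.
    covariates : sequence of str
        Confounders to adjust for; dummy-coded via
        :meth:`Cohort.design_matrix`.
    """

    def __init__(self, cohort: Cohort, covariates=DEFAULT_COVARIATES):
        self.cohort = cohort
        self.covariates = tuple(covariates)

    def _log_magnitudes(self, mk: str) -> np.ndarray:
        y = self.cohort.markers[mk].to_numpy(dtype=float)
        if self.cohort.marker_meta.loc[mk, "log_transform"]:
            pos = y[np.isfinite(y) & (y > 0)]
            floor = pos.min() / 2.0 if pos.size else 1.0
            y = np.log(np.clip(y, floor, None))
        return y

    def fit(self, responders_only: bool = False) -> "MarkerComparisonResults":
        """Fit magnitude (and, when calls exist, response-rate) models.

        Returns results over strata {all} + severity levels with >= 1
        participant per HIV group. Contrasts for empty stratum-by-group
        cells are reported as undefined (NaN), not raised.
        """
        meta = self.cohort.metadata
        covars = self.cohort.design_matrix(self.covariates)
        rows = []
        strata_counts = meta.groupby(["severity", "hiv_status"]).size()

        for mk in self.cohort.markers.columns:
            logged = bool(self.cohort.marker_meta.loc[mk, "log_transform"])
            estimand = "gmr_magnitude" if logged else "mean_difference"
            y = self._log_magnitudes(mk)
            keep = np.isfinite(y)
            if responders_only and self.cohort.responses is not None \
                    and mk in self.cohort.responses.columns:
                keep &= (self.cohort.responses[mk] == 1).to_numpy()
            rows.extend(
                self._magnitude_rows(mk, estimand, y, keep, meta, covars,
                                     strata_counts, logged)
            )
            if self.cohort.responses is not None \
                    and mk in self.cohort.responses.columns and not responders_only:
                rows.extend(
                    self._response_rows(mk, meta, covars, strata_counts)
                )

        frame = pd.DataFrame(rows)
        if not frame.empty:
            fam = self.cohort.marker_meta["assay_family"]
            frame["family"] = frame["marker_id"].map(fam)
            frame["q"] = np.nan
            for _, idx in frame.groupby(
                ["estimand", "stratum", "family"], sort=False
            ).groups.items():
                sub = frame.loc[idx, "p"]
                ok = sub.notna()
                if ok.any():
                    frame.loc[sub.index[ok], "q"] = bh_adjust(sub[ok].to_numpy())
            frame["significant"] = (frame["p"] <= 0.05) & (frame["q"] <= 0.2)
        return MarkerComparisonResults(frame, self)

    def _magnitude_rows(self, mk, estimand, y, keep, meta, covars,
                        strata_counts, logged):
        sub_meta, sub_cov, y = meta[keep], covars[keep], y[keep]
        out = []
        tf = np.exp if logged else (lambda v: v)
        # overall: no interaction
        hiv = (sub_meta["hiv_status"] == "PLWH").astype(float)
        X_cols = {"const": 1.0, "hiv": hiv}
        for s in SEVERITIES[1:]:
            if (sub_meta["severity"] == s).any():
                X_cols[f"sev_{s}"] = (sub_meta["severity"] == s).astype(float)
        X = pd.DataFrame(X_cols, index=sub_meta.index).join(sub_cov)
        try:
            res = sm.OLS(y, X.to_numpy()).fit()
            j = list(X.columns).index("hiv")
            ci = res.conf_int()
            out.append(_row(mk, "all", estimand, tf(res.params[j]),
                            tf(ci[j, 0]), tf(ci[j, 1]), res.pvalues[j]))
        except Exception:
            out.append(_row(mk, "all", estimand))
        # stratified via interaction contrasts
        Xi, present = _interaction_design(sub_meta, sub_cov)
        try:
            res = sm.OLS(y, Xi.to_numpy()).fit()
        except Exception:
            res = None
        for s in SEVERITIES:
            ok = (
                res is not None
                and strata_counts.get((s, "PLWH"), 0) >= 2
                and strata_counts.get((s, "PWOH"), 0) >= 2
            )
            if not ok:
                out.append(_row(mk, s, estimand))
                continue
            c = _stratum_contrast(list(Xi.columns), s)
            ct = res.t_test(c)
            est = float(np.asarray(ct.effect).ravel()[0])
            lo, hi = ct.conf_int()[0]
            out.append(_row(mk, s, estimand, tf(est), tf(lo), tf(hi),
                            float(ct.pvalue)))
        return out

    def _response_rows(self, mk, meta, covars, strata_counts):
        r = self.cohort.responses[mk]
        keep = r.notna().to_numpy()
        y = r[keep].to_numpy(dtype=float)
        sub_meta, sub_cov = meta[keep], covars[keep]
        out = []
        if len(np.unique(y)) < 2:
            return [_row(mk, s, "odds_ratio_response")
                    for s in ("all",) + SEVERITIES]
        hiv = (sub_meta["hiv_status"] == "PLWH").astype(float)
        X_cols = {"const": 1.0, "hiv": hiv}
        for s in SEVERITIES[1:]:
            if (sub_meta["severity"] == s).any():
                X_cols[f"sev_{s}"] = (sub_meta["severity"] == s).astype(float)
        X = pd.DataFrame(X_cols, index=sub_meta.index).join(sub_cov)
        try:
            res = FirthLogit(y, X).fit()
            j = list(X.columns).index("hiv")
            ci = np.exp(res.conf_int()[j])
            out.append(_row(mk, "all", "odds_ratio_response",
                            float(np.exp(res.params[j])), float(ci[0]),
                            float(ci[1]), float(res.pvalues[j])))
        except Exception:
            out.append(_row(mk, "all", "odds_ratio_response"))
        Xi, _ = _interaction_design(sub_meta, sub_cov)
        try:
            resi = FirthLogit(y, Xi).fit()
        except Exception:
            resi = None
        for s in SEVERITIES:
            ok = (
                resi is not None
                and strata_counts.get((s, "PLWH"), 0) >= 2
                and strata_counts.get((s, "PWOH"), 0) >= 2
            )
            if not ok:
                out.append(_row(mk, s, "odds_ratio_response"))
                continue
            c = _stratum_contrast(list(Xi.columns), s)
            est, se, p = resi.contrast(c)
            z = stats.norm.ppf(0.975)
            out.append(_row(mk, s, "odds_ratio_response", float(np.exp(est)),
                            float(np.exp(est - z * se)),
                            float(np.exp(est + z * se)), p))
        return out


def _row(mk, stratum, estimand, est=np.nan, lo=np.nan, hi=np.nan, p=np.nan):
    return {
        "marker_id": mk, "stratum": stratum, "estimand": estimand,
        "estimate": est, "ci_lower": lo, "ci_upper": hi, "p": p,
    }


class MarkerComparisonResults:
    """Tidy per-marker comparison results with BH q-values."""

    def __init__(self, frame: pd.DataFrame, model: MarkerComparison):
        self.frame = frame
        self.model = model

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"].fillna(False)].copy()

    def summary(self, stratum: str | None = None) -> pd.DataFrame:
        f = self.frame if stratum is None else self.frame[
            self.frame["stratum"] == stratum
        ]
        cols = ["marker_id", "stratum", "estimand", "estimate",
                "ci_lower", "ci_upper", "p", "q", "significant"]
        return f[cols].reset_index(drop=True)
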