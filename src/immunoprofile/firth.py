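"""Firth penalized (bias-reduced) logistic regression.

Maximizes the Jeffreys-prior penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log |I(beta)|

by Newton iterations on the modified score U*(beta) = X' (y - p + h (1/2 - p)),
where h are the hat values of the weighted design. The penalty keeps the
estimates finite even under complete separation, where the ordinary MLE
diverges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = ["FirthLogit", "FirthLogitResults"]


class FirthLogit:
    """Firth logistic regression model.

    Parameters
    ----------
    endog : array-like of 0/1, shape (n,)
    exog : array-like, shape (n, k)
        Design matrix; pass an explicit intercept column. A DataFrame's
        column names are carried through to the results.

    Examples
    --------
    >>> import numpy as np
    >>> from immunoprofile import FirthLogit
    >>> rng = np.random.default_rng(0)
    >>> x = rng.normal(size=(200, 1))
    >>> y = rng.random(200) < 1 / (1 + np.exp(-(-1 + 0.5 * x[:, 0])))
    >>> res = FirthLogit(y, np.column_stack([np.ones(200), x])).fit()
    >>> res.params.shape
    (2,)
    """

    def __init__(self, endog, exog, names=None):
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("endog is constant")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise np.linalg.LinAlgError("exog is rank deficient")
        self.exog_names = names or [f"x{i}" for i in range(self.exog.shape[1])]

    def _penalized_loglike(self, beta):
        eta = self.exog @ beta
        ll = np.sum(self.endog * eta - np.logaddexp(0.0, eta))
        p = expit(eta)
        w = p * (1.0 - p)
        info = self.exog.T @ (self.exog * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    def fit(self, maxiter: int = 50, tol: float = 1e-6) -> "FirthLogitResults":
        """Newton iterations with step-halving; converges when
        max|delta beta| < tol."""
        X, y = self.exog, self.endog
        n, k = X.shape
        beta = np.zeros(k)
        ll = self._penalized_loglike(beta)
        trace = []
        for it in range(maxiter):
            eta = X @ beta
            p = expit(eta)
            w = p * (1.0 - p)
            Xw = X * w[:, None]
            info = X.T @ Xw
            info_inv = np.linalg.inv(info)
            # hat values of the weighted least-squares design
            h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv,
                          X * np.sqrt(w)[:, None])
            score = X.T @ (y - p + h * (0.5 - p))
            step = info_inv @ score
            # step-halving on the penalized log-likelihood
            for _ in range(15):
                cand = beta + step
                ll_new = self._penalized_loglike(cand)
                if ll_new >= ll - 1e-10:
                    break
                step = step / 2.0
            delta = np.max(np.abs(cand - beta))
            beta, ll = cand, ll_new
            trace.append((it, float(delta), float(ll)))
            if delta < tol:
                break
        else:
            raise RuntimeError(
                f"Firth fit did not converge in {maxiter} iterations; "
                f"trace: {trace[-5:]}"
            )
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        return FirthLogitResults(self, beta, cov, int(it) + 1, float(ll))


class FirthLogitResults:
    """Estimates, Wald covariance and tests from a :class:`FirthLogit` fit."""

    def __init__(self, model, params, cov_params, n_iter, penalized_llf):
        self.model = model
        self.params = params
        self.cov = cov_params
        self.n_iter = n_iter
        self.penalized_llf = penalized_llf

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov))

    @property
    def tvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        """Two-sided Wald p-values."""
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def conf_int(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = np.exp(self.conf_int(alpha))
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_lower": ci[:, 0],
                "ci_upper": ci[:, 1],
                "p": self.pvalues,
            },
            index=self.model.exog_names,
        )

    def contrast(self, c):
        """Wald test of a linear contrast c'beta; returns (estimate, se, p)."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
        return est, se, p

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "z": self.tvalues,
                "P>|z|": self.pvalues,
                "[0.025": ci[:, 0],
                "0.975]": ci[:, 1],
            },
            index=self.model.exog_names,
        )
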