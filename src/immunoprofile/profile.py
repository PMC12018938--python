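"""Quantile polar-profile summaries and the direction-projection-permutation
(DiProPerm) global two-sample test.

The DiProPerm construction used here: the discriminating direction is the
unit-normalized difference of group mean vectors; samples are projected on
it and the two projected samples compared by a two-sample t statistic; the
null distribution is obtained by recomputing direction and statistic under
random relabelings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import NormalizedMatrix

__all__ = ["QuantileProfile", "quantile_ranks", "group_mean_quantiles",
           "DiProPerm", "DiProPermResults"]


@dataclass
class QuantileProfile:
    """Per-marker participant quantile ranks scaled to [0, 1]."""

    ranks: pd.DataFrame
    reference: float = 0.5


def quantile_ranks(matrix) -> QuantileProfile:
    """Rank participants per marker (average ranks for ties) and scale by
    (rank - 1)/(n - 1) so the support is exactly [0, 1]."""
    df = matrix.values if isinstance(matrix, NormalizedMatrix) else pd.DataFrame(matrix)
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 participants to rank")
    ranks = df.apply(lambda col: (rankdata(col) - 1.0) / (n - 1.0))
    return QuantileProfile(ranks)


def group_mean_quantiles(profile: QuantileProfile, groups, strata=None) -> pd.DataFrame:
    """Mean quantile per marker x group (x stratum): the polar-plot table."""
    groups = pd.Series(np.asarray(groups), index=profile.ranks.index, name="group")
    if groups.isna().any():
        raise ValueError("group labels must cover all participants")
    frames = []
    long = profile.ranks.join(groups)
    if strata is None:
        g = long.groupby("group", observed=True).mean()
        out = g.T.reset_index().melt(
            id_vars="index", var_name="group", value_name="mean_quantile"
        ).rename(columns={"index": "marker_id"})
        out["stratum"] = "all"
        frames.append(out)
    else:
        strata = pd.Series(np.asarray(strata), index=profile.ranks.index,
                           name="stratum")
        long = long.join(strata)
        g = long.groupby(["group", "stratum"], observed=True).mean()
        if g.isna().all(axis=1).any():
            raise ValueError("empty group x stratum cell")
        out = (
            g.stack().rename("mean_quantile").reset_index()
            .rename(columns={"level_2": "marker_id"})
        )
        frames.append(out)
    result = pd.concat(frames, ignore_index=True)
    return result[["marker_id", "group", "stratum", "mean_quantile"]]


def _t_stats(S: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Column-wise two-sample t over projection scores.

    S is (n, B) projection scores; G is (B, n) 0/1 group-1 indicators so
    that column b of S is evaluated under labeling b.
    """
    n1 = G.sum(axis=1)
    n2 = G.shape[1] - n1
    m1 = np.einsum("bn,nb->b", G, S) / n1
    m2 = np.einsum("bn,nb->b", 1.0 - G, S) / n2
    sq = S * S
    v1 = (np.einsum("bn,nb->b", G, sq) - n1 * m1**2) / (n1 - 1)
    v2 = (np.einsum("bn,nb->b", 1.0 - G, sq) - n2 * m2**2) / (n2 - 1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, (m1 - m2) / se, 0.0)


class DiProPerm:
    """Global test of any distributional difference between two groups.

    Parameters
    ----------
    matrix : NormalizedMatrix or DataFrame or ndarray
        Complete participants x markers data.
    labels : array-like
        Binary group labels (any two values).
    """

    def __init__(self, matrix, labels):
        X = (matrix.values if isinstance(matrix, NormalizedMatrix)
             else pd.DataFrame(matrix)).to_numpy(dtype=float)
        labels = np.asarray(labels)
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ValueError("labels must take exactly two values")
        g = (labels == uniq[0]).astype(float)
        if g.sum() < 2 or (1 - g).sum() < 2:
            raise ValueError("each group needs at least 2 members")
        self.X = X
        self.g = g
        self.group_names = (str(uniq[0]), str(uniq[1]))

    @staticmethod
    def _direction(X, g):
        d = X[g == 1].mean(axis=0) - X[g == 0].mean(axis=0)
        norm = np.linalg.norm(d)
        return d / norm if norm > 0 else d

    def fit(self, B: int = 1000, seed: int | None = None) -> "DiProPermResults":
        """Permutation test with B >= 100 relabelings; one-sided (>=) with the
        +1 correction so that p in [1/(B+1), 1]."""
        if B < 100:
            raise ValueError("B must be at least 100")
        rng = np.random.default_rng(seed)
        X, g = self.X, self.g
        d = self._direction(X, g)
        s_obs = X @ d
        obs = float(_t_stats(s_obs[:, None], g[None, :])[0])

        n = len(g)
        G = np.empty((B, n))
        for b in range(B):
            G[b] = rng.permutation(g)
        # direction per permutation: D = (G X)/n1 - ((1-G) X)/n2, rows unit-norm
        n1, n2 = g.sum(), n - g.sum()
        D = (G @ X) / n1 - ((1.0 - G) @ X) / n2
        norms = np.linalg.norm(D, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        D /= norms
        S = X @ D.T  # (n, B)
        perm = _t_stats(S, G)
        p = (1.0 + np.sum(perm >= obs)) / (1.0 + B)
        return DiProPermResults(obs, perm, float(p), d, B, self.group_names)


@dataclass
class DiProPermResults:
    """Observed statistic, permutation null and p-value of a DiProPerm fit."""

    statistic: float
    null_distribution: np.ndarray
    pvalue: float
    direction: np.ndarray
    n_permutations: int
    group_names: tuple

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "statistic": self.statistic,
                "p_value": self.pvalue,
                "n_permutations": self.n_permutations,
                "group_1": self.group_names[0],
                "group_2": self.group_names[1],
            }
        )
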