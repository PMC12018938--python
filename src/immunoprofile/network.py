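"""Spearman correlation networks and their group comparison.

Builds stratum- and HIV-group-specific Spearman matrices, retains edges at
FDR < 10% and |rho| > 0.70 ("restricted" network), clusters markers by
Girvan-Newman edge betweenness, estimates the "unrestricted" network size
(the number of non-null correlations) as (1 - pi0) x m(m-1)/2 with a Storey
smoother pi0, and compares network statistics between groups by size-matched
subsampling of the larger group.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .compare import bh_adjust
from .preprocess import NormalizedMatrix

__all__ = [
    "n_pairs",
    "spearman_matrix",
    "exact_spearman_pvalue",
    "CorrelationNetwork",
    "build_restricted_network",
    "cluster_edge_betweenness",
    "estimate_pi0",
    "estimate_unrestricted_size",
    "subsample_comparison",
    "SubsampleSummary",
    "identity_line_summary",
    "pct_below_identity",
]


def n_pairs(m: int) -> int:
    """Number of marker pairs m(m-1)/2 (1540 for the 56-marker panel)."""
    if m < 2:
        raise ValueError("need at least 2 markers")
    return m * (m - 1) // 2


def exact_spearman_pvalue(x, y) -> tuple[float, float]:
    """Exact two-sided Spearman test by enumerating all rank permutations.

    Valid for small tie-free samples; the null distribution of rho is built
    from all n! permutations in chunks. Returns (rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(stats.spearmanr(x, y).statistic)
    denom = n * (n * n - 1) / 6.0
    count = 0
    total = math.factorial(n)
    chunk = []
    m_abs = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 40320:
            d = np.asarray(chunk) - rx
            rhos = 1.0 - (d * d).sum(axis=1) / denom
            count += int(np.sum(np.abs(rhos) >= m_abs))
            chunk = []
    if chunk:
        d = np.asarray(chunk) - rx
        rhos = 1.0 - (d * d).sum(axis=1) / denom
        count += int(np.sum(np.abs(rhos) >= m_abs))
    return rho_obs, count / total


def spearman_matrix(matrix, exact_max_n: int = 10):
    """Pairwise Spearman rho and two-sided p over all marker pairs.

    p-values use the exact permutation null when n <= ``exact_max_n`` and
    the data are tie-free, and the t approximation
    t = rho sqrt((n-2)/(1-rho^2)) otherwise. Pairs involving a constant
    marker are flagged undefined (NaN). Returns (rho, p) DataFrames.
    """
    df = matrix.values if isinstance(matrix, NormalizedMatrix) else pd.DataFrame(matrix)
    n, m = df.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    X = df.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    const = sd == 0
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)

    tie_free = all(len(np.unique(X[:, j])) == n for j in range(m))
    if n <= exact_max_n and tie_free:
        p = np.full((m, m), np.nan)
        for i in range(m):
            for j in range(i + 1, m):
                _, pv = exact_spearman_pvalue(X[:, i], X[:, j])
                p[i, j] = p[j, i] = pv
    else:
        r = np.clip(rho, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p[np.isclose(np.abs(r), 1.0)] = 0.0
        p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.nan)
    idx = df.columns
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


@dataclass
class CorrelationNetwork:
    """A marker correlation network with retained edges and size statistics."""

    markers: list
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    edges: list = field(default_factory=list)
    clusters: list | None = None
    pi0: float | None = None

    @property
    def restricted_size(self) -> int:
        return len(self.edges)

    @property
    def average_degree(self) -> float:
        return 2.0 * self.restricted_size / len(self.markers)

    @property
    def unrestricted_size(self) -> float | None:
        if self.pi0 is None:
            return None
        return (1.0 - self.pi0) * n_pairs(len(self.markers))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.markers)
        for a, b, r in self.edges:
            g.add_edge(a, b, rho=r)
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_a": a, "marker_b": b, "rho": r,
             "p": self.p.loc[a, b], "q": self.q.loc[a, b]}
            for a, b, r in self.edges
        ]
        return pd.DataFrame(rows, columns=["marker_a", "marker_b", "rho", "p", "q"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)


def build_restricted_network(rho: pd.DataFrame, p: pd.DataFrame,
                             fdr: float = 0.10, rho_min: float = 0.70,
                             cluster: bool = True) -> CorrelationNetwork:
    """Retain an edge iff its BH q-value (over all pairs) < fdr and
    |rho| > rho_min."""
    markers = list(rho.columns)
    m = len(markers)
    iu = np.triu_indices(m, k=1)
    rmat = rho.to_numpy()
    pvec = p.to_numpy()[iu]
    qvec = np.full_like(pvec, np.nan)
    ok = ~np.isnan(pvec)
    if ok.any():
        qvec[ok] = bh_adjust(pvec[ok])
    qmat = np.full((m, m), np.nan)
    qmat[iu] = qvec
    qmat[(iu[1], iu[0])] = qvec
    q = pd.DataFrame(qmat, index=markers, columns=markers)
    rvec = rmat[iu]
    keep = ok & ~np.isnan(rvec) & (qvec < fdr) & (np.abs(rvec) > rho_min)
    edges = [
        (markers[i], markers[j], float(r))
        for i, j, r in zip(iu[0][keep], iu[1][keep], rvec[keep])
    ]
    net = CorrelationNetwork(markers, rho, p, q, edges)
    if cluster:
        net.clusters = cluster_edge_betweenness(net)
    return net


def cluster_edge_betweenness(network: CorrelationNetwork | nx.Graph) -> list:
    """Girvan-Newman edge-betweenness clustering.

    Returns the dendrogram cut maximizing modularity (ties toward fewer
    clusters); isolated markers come back as singleton clusters.
    """
    g = network.graph() if isinstance(network, CorrelationNetwork) else network
    if g.number_of_edges() == 0:
        return [frozenset([n]) for n in g.nodes]
    components = [frozenset(c) for c in nx.connected_components(g)]
    best = components
    best_mod = nx.algorithms.community.modularity(g, components)
    for partition in nx.algorithms.community.girvan_newman(g):
        part = [frozenset(c) for c in partition]
        mod = nx.algorithms.community.modularity(g, part)
        if mod > best_mod + 1e-12:
            best, best_mod = part, mod
    return sorted(best, key=lambda c: (-len(c), sorted(c)[0]))


def estimate_pi0(p, lambdas=None, method: str = "smoother",
                 fixed_lambda: float = 0.5) -> float:
    """Proportion of true-null hypotheses from a p-value vector.

    ``smoother``: Storey's estimate pi0(lambda) = #{p > lambda}/(m (1-lambda))
    on the grid 0.05..0.95, cubic-smoothed and evaluated at the largest
    lambda, clipped to [0, 1]. ``fixed``: pi0(fixed_lambda).
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if method == "fixed":
        lam = fixed_lambda
        return float(np.clip(np.mean(p > lam) / (1 - lam), 0.0, 1.0))
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas)
    pi0_lam = np.array([np.mean(p > l) / (1 - l) for l in lambdas])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, 0.0, 1.0))


def estimate_unrestricted_size(p, m: int, method: str = "smoother"):
    """pi0-based network size: (1 - pi0) m(m-1)/2, plus the average degree.

    Returns (pi0, size, average_degree) with size and degree unrounded;
    round to nearest integer for reporting.
    """
    pi0 = estimate_pi0(p, method=method)
    size = (1.0 - pi0) * n_pairs(m)
    return pi0, size, 2.0 * size / m


def _upper_vec(mat: pd.DataFrame) -> np.ndarray:
    a = mat.to_numpy()
    iu = np.triu_indices_from(a, k=1)
    return a[iu]


def network_statistic(values: pd.DataFrame, statistic: str,
                      fdr: float = 0.10, rho_min: float = 0.70) -> float:
    """One of {restricted_size, unrestricted_size, average_degree} on a
    participants x markers table (average degree is for the unrestricted
    network, matching how the summary tables report it)."""
    rho, p = spearman_matrix(values)
    m = values.shape[1]
    if statistic == "restricted_size":
        net = build_restricted_network(rho, p, fdr, rho_min, cluster=False)
        return float(net.restricted_size)
    pvec = _upper_vec(p)
    pi0, size, avg = estimate_unrestricted_size(pvec[~np.isnan(pvec)], m)
    return float(size) if statistic == "unrestricted_size" else float(avg)


@dataclass
class SubsampleSummary:
    """Distribution of a network statistic over size-matched subsamples."""

    statistic: str
    values: np.ndarray
    reference_value: float
    n_excluded: int = 0

    @property
    def prob_pwoh_gt_plwh(self) -> float:
        """Fraction of subsamples strictly exceeding the reference (PLWH)
        value; ties count as non-exceedance."""
        return float(np.mean(self.values > self.reference_value))

    def summary(self) -> pd.Series:
        v = self.values
        return pd.Series(
            {
                "statistic": self.statistic,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
                "median": float(np.median(v)),
                "iqr_lower": float(np.percentile(v, 25)),
                "iqr_upper": float(np.percentile(v, 75)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "reference_value": self.reference_value,
                "prob_pwoh_gt_plwh": self.prob_pwoh_gt_plwh,
                "n_subsamples": int(v.size),
                "n_excluded": self.n_excluded,
            }
        )


def subsample_comparison(pwoh_values: pd.DataFrame, plwh_values: pd.DataFrame,
                         statistic: str = "restricted_size", R: int = 10_000,
                         seed: int | None = None, fdr: float = 0.10,
                         rho_min: float = 0.70) -> SubsampleSummary:
    """Compare a network statistic between groups by subsampling.

    Draws R subsamples without replacement from the PWOH rows, each of the
    PLWH sample size, recomputes the statistic on each, and reports the
    distribution plus Prob(PWOH > PLWH). Subsamples on which the statistic
    is undefined are excluded with a count.
    """
    n_plwh = len(plwh_values)
    if len(pwoh_values) < n_plwh:
        raise ValueError("PWOH group smaller than PLWH group")
    rng = np.random.default_rng(seed)
    ref = network_statistic(plwh_values, statistic, fdr, rho_min)
    vals = []
    excluded = 0
    idx = np.arange(len(pwoh_values))
    for _ in range(R):
        take = rng.choice(idx, size=n_plwh, replace=False)
        sub = pwoh_values.iloc[take]
        try:
            vals.append(network_statistic(sub, statistic, fdr, rho_min))
        except (ValueError, FloatingPointError):
            excluded += 1
    return SubsampleSummary(statistic, np.asarray(vals), ref, excluded)


def pct_below_identity(n_below: int, total: int) -> float:
    """Percentage, to one decimal, of pairs strictly below the identity line."""
    return round(100.0 * n_below / total, 1)


def identity_line_summary(rho_a: pd.DataFrame, rho_b: pd.DataFrame) -> dict:
    """Compare two correlation matrices pair by pair.

    Counts pairs with rho_b strictly below rho_a (below the identity line
    when plotting B against A) and the fraction of strictly negative
    coefficients in each matrix.
    """
    if list(rho_a.columns) != list(rho_b.columns):
        raise ValueError("marker sets must match")
    a = _upper_vec(rho_a)
    b = _upper_vec(rho_b)
    total = a.size
    n_below = int(np.sum(b < a))
    return {
        "n_pairs": total,
        "n_below": n_below,
        "pct_below": pct_below_identity(n_below, total),
        "pct_negative_a": round(100.0 * np.mean(a < 0), 2),
        "pct_negative_b": round(100.0 * np.mean(b < 0), 2),
    }
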