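"""Group-comparison statistics for hierarchical wingbeat data.

Implements the statistical battery used to contrast microhabitats:
sequential (Type-I) ANOVA with the habitat factor entered first and the
nested factors (species, individual, flight, wingbeat index) absorbing the
remaining structure; MANOVA via Wilks' lambda with Rao's F approximation;
phylogenetic ANOVA whose null F distribution is generated by simulating
Brownian-motion trait evolution on the species tree; simple linear
regression, Pearson correlation and the Wilcoxon rank-sum test; and the
percent group contrasts used for reporting.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "RegressionFit",
    "PhyloAnovaResult",
    "sequential_anova",
    "manova_wilks",
    "phylogenetic_anova",
    "tree_vcv",
    "linear_regression",
    "pearson_correlation",
    "wilcoxon_rank_sum",
    "percent_difference",
]


# ---------------------------------------------------------------------------
# Sequential (Type-I) ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Sequential ANOVA decomposition; one row per factor plus residual."""

    table: pd.DataFrame  # index: factors + 'residual'; columns df, ss, ms, F, p
    response: str
    factors: tuple[str, ...]

    @property
    def total_ss(self) -> float:
        return float(self.table["ss"].sum())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Sequential ANOVA of {self.response}\n{self.table.to_string()}"


def _dummy(col: pd.Series) -> np.ndarray:
    levels = pd.unique(col)
    return (col.to_numpy()[:, None] == levels[None, :]).astype(float)


def sequential_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
) -> AnovaTable:
    """Type-I (sequential) ANOVA in the given factor order.

    Each factor is added to the design in turn (as fixed-effect dummies);
    its sum of squares is the drop in residual SS when it enters, with
    degrees of freedom equal to the rank gained.  F statistics test each
    factor against the final residual mean square.  With nested labels
    (individuals within species, flights within individuals) the sequential
    decomposition charges each level only with variation not explained by
    the factors before it.
    """
    if response not in data.columns:
        raise KeyError(f"response {response!r} not in data")
    for f in factors:
        if f not in data.columns:
            raise KeyError(f"factor {f!r} not in data")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    total_ss = float(np.sum((y - y.mean()) ** 2))

    X = np.ones((n, 1))
    rank = 1
    resid_ss = total_ss
    rows = []
    for f in factors:
        X = np.hstack([X, _dummy(data[f])])
        beta, _, new_rank, _ = np.linalg.lstsq(X, y, rcond=None)
        new_rank = int(np.linalg.matrix_rank(X))
        rss = float(np.sum((y - X @ beta) ** 2))
        df_f = new_rank - rank
        if df_f < 1:
            raise ValueError(
                f"factor {f!r} is completely confounded with factors before it"
            )
        rows.append((f, df_f, max(resid_ss - rss, 0.0)))
        rank, resid_ss = new_rank, rss

    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom; the model is saturated")
    ms_resid = resid_ss / df_resid

    out = []
    for f, df_f, ss in rows:
        if total_ss == 0.0 or ms_resid == 0.0:
            F, p = 0.0, 1.0
        else:
            F = (ss / df_f) / ms_resid
            p = float(sps.f.sf(F, df_f, df_resid))
        out.append({"factor": f, "df": df_f, "ss": ss, "ms": ss / df_f, "F": F, "p": p})
    out.append(
        {
            "factor": "residual",
            "df": df_resid,
            "ss": resid_ss,
            "ms": ms_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(out).set_index("factor")
    return AnovaTable(table=table, response=response, factors=tuple(factors))


# ---------------------------------------------------------------------------
# MANOVA (Wilks' lambda)
# ---------------------------------------------------------------------------


def manova_wilks(
    data: pd.DataFrame,
    responses: list[str],
    group: str,
) -> tuple[float, float, float]:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    lambda = det(W) / det(W + B) with W, B the within- and between-group
    SSCP matrices.  Returns (lambda, F, p).
    """
    Y = data[list(responses)].to_numpy(dtype=float)
    g = data[group]
    labels = pd.unique(g)
    n, p = Y.shape
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= p + k - 1:
        raise ValueError("too few observations for the number of responses")
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        Yg = Y[(g == lab).to_numpy()]
        mg = Yg.mean(axis=0)
        W += (Yg - mg).T @ (Yg - mg)
        B += len(Yg) * np.outer(mg - grand, mg - grand)
    sign, logdet_w = np.linalg.slogdet(W)
    if sign <= 0:
        raise ValueError(
            "within-group covariance is singular; drop collinear responses"
        )
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = k - 1
    m = n - 1 - (p + k) / 2.0
    num = p**2 * q**2 - 4.0
    den = p**2 + q**2 - 5.0
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    df1 = p * q
    df2 = m * t - df1 / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return lam, float(F), pval


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA (Brownian-motion simulation)
# ---------------------------------------------------------------------------


@dataclass
class PhyloAnovaResult:
    """Phylogenetic ANOVA via trait simulation on the species tree."""

    f_observed: float
    f_null: np.ndarray  # simulated null sample
    p_phylo: float
    p_standard: float  # parametric one-way ANOVA p, for comparison
    n_sim: int
    tree_newick: str


def tree_vcv(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion variance-covariance matrix of the tip taxa.

    C[i, j] is the shared root-to-MRCA path length of tips i and j.  Trees
    without branch lengths fall back to unit lengths.
    """
    tree = tree.clone(depth=1)
    for e in tree.preorder_edge_iter():
        if e.length is None and e.head_node is not tree.seed_node:
            e.length = 1.0
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    tip = {}
    for leaf in tree.leaf_node_iter():
        tip[leaf.taxon.label] = leaf
    missing = [t for t in taxa if t not in tip]
    if missing:
        raise ValueError(f"tree tips do not match species names; missing {missing}")
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    pdm = tree.phylogenetic_distance_matrix()
    k = len(taxa)
    C = np.zeros((k, k))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                C[i, j] = depth[tip[a]]
            else:
                d = pdm.patristic_distance(tip[a].taxon, tip[b].taxon)
                C[i, j] = (depth[tip[a]] + depth[tip[b]] - d) / 2.0
    return C


def _oneway_f(values: np.ndarray, group_codes: np.ndarray, k: int):
    """Vectorized one-way ANOVA F over the last axis grouping; values may be
    (n_sim, n) or (n,)."""
    V = np.atleast_2d(values)
    n = V.shape[1]
    grand = V.mean(axis=1, keepdims=True)
    ss_total = np.sum((V - grand) ** 2, axis=1)
    ss_between = np.zeros(V.shape[0])
    for c in range(k):
        sel = group_codes == c
        mg = V[:, sel].mean(axis=1)
        ss_between += sel.sum() * (mg - grand[:, 0]) ** 2
    df1 = k - 1
    df2 = n - k
    ss_within = ss_total - ss_between
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    return F, df1, df2


def phylogenetic_anova(
    values,
    groups,
    tree,
    species: list[str] | None = None,
    n_sim: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PhyloAnovaResult:
    """ANOVA of species means with a Brownian-motion simulated null.

    Parameters
    ----------
    values : array-like
        One trait value per species (species means).
    groups : array-like
        Group label per species (e.g. canopy / understory).
    tree : dendropy.Tree or newick str
        Species phylogeny; tip labels must cover the species.
    species : list of str, optional
        Species names aligning ``values`` with tree tips.  Defaults to the
        tree's taxon order, in which case values must already be ordered.
    n_sim : int
        Number of Brownian-motion simulations for the null F sample
        (minimum 100).
    seed : int or Generator
        Reproducibility of the simulated null.

    The observed one-way F is compared against F statistics of traits
    simulated under Brownian motion on the tree, with the BM rate estimated
    from the observed data by GLS; the p-value is the +1-corrected fraction
    of simulated F at least as large.  Because F is invariant to trait
    location and scale, the estimated rate does not affect the p-value, but
    it is used so the null sample is on the data's scale.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    x = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if species is None:
        species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(x) != len(species) or len(groups) != len(species):
        raise ValueError("values, groups and species must have equal length")
    C = tree_vcv(tree, list(species))

    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    f_obs, df1, df2 = _oneway_f(x, codes, k)
    f_obs = float(f_obs[0])
    p_standard = float(sps.f.sf(f_obs, df1, df2))

    # GLS estimate of the BM rate from the observed tip data
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(x))
    mu = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    resid = x - mu
    rate = float(resid @ Cinv @ resid) / max(len(x) - 1, 1)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(x)))
    sims = rng.standard_normal((n_sim, len(x))) @ Lc.T * np.sqrt(rate)
    f_null, _, _ = _oneway_f(sims, codes, k)
    f_null = f_null[np.isfinite(f_null)]
    p_phylo = (1.0 + np.sum(f_null >= f_obs)) / (len(f_null) + 1.0)
    return PhyloAnovaResult(
        f_observed=f_obs,
        f_null=f_null,
        p_phylo=float(p_phylo),
        p_standard=p_standard,
        n_sim=n_sim,
        tree_newick=tree.as_string(schema="newick").strip(),
    )


# ---------------------------------------------------------------------------
# Regression, correlation, rank tests, contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS fit with the usual report statistics."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    residual_sd: float
    df1: int = 1
    df2: int = 0


def linear_regression(x, y) -> RegressionFit:
    """Ordinary least-squares line of y on x with R^2, F and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    df2 = n - 2
    F = (df2 * r2 / (1.0 - r2)) if r2 < 1.0 else np.inf
    resid = y - (res.intercept + res.slope * x)
    resid_sd = float(np.sqrt(np.sum(resid**2) / df2)) if df2 > 0 else 0.0
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_statistic=float(F),
        p_value=float(res.pvalue),
        n=n,
        residual_sd=resid_sd,
        df1=1,
        df2=df2,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be non-constant")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first group.  The p-value is exact (full
    enumeration) for combined samples up to 25 without ties, and a normal
    approximation with tie correction (no continuity correction)
    otherwise, so identical groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    W = float(ranks[:na].sum())
    ties = np.unique(combined).size < combined.size
    if not ties and na + nb <= 25:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return W, float(res.pvalue)
    # normal approximation with tie correction
    U = W - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    n = na + nb
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return W, 1.0
    z = (U - mu) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return W, min(p, 1.0)


def percent_difference(mean_a: float, mean_b: float, ndigits: int | None = None) -> float:
    """Percent by which ``mean_a`` exceeds ``mean_b``: 100 (a - b) / b.

    ``ndigits`` rounds the result to the reporting precision (0 for whole
    percent); ``None`` leaves it unrounded.
    """
    if mean_b == 0:
        raise ValueError("baseline mean is zero; percent difference undefined")
    pct = 100.0 * (mean_a - mean_b) / mean_b
    if ndigits is not None:
        pct = round(pct, ndigits)
    return float(pct)
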