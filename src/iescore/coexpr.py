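"""Weighted coexpression network analysis.

Implements the WGCNA-style screening stage: variance filtering, unsigned
soft-thresholded adjacency |r|^beta with a scale-free topology fit to pick
beta, topological overlap (TOM) similarity, average-linkage module detection
with a static height cut, module eigengenes, and eigengene-trait
correlation. The aim is to flag coexpression modules whose eigengene tracks
a clinical trait (e.g. response to therapy), not to reproduce any particular
reference partition: dynamic tree cut is deliberately replaced by a static
cut, so module counts depend on ``cut_height`` and ``min_module_size``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

#: WGCNA-style module colors, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


def variance_filter(expr: pd.DataFrame, quantile: float = 0.25) -> pd.DataFrame:
    """Keep the genes whose variance ranks in the top ``quantile`` fraction.

    Retains genes with variance >= the (1 - quantile) variance quantile;
    with tie-free variances that is ceil(quantile * n_genes) genes.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    variances = expr.var(axis=1, ddof=1)
    if variances.max() == variances.min():
        raise ValueError("all genes have equal variance; filtering is undefined")
    threshold = variances.quantile(1 - quantile, interpolation="higher")
    return expr.loc[variances >= threshold]


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |pearson r|^beta, zero diagonal."""
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Sign-adjusted R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins of log10(k);
    log10(bin frequency) is regressed on log10(mean k per bin); empty bins
    are dropped. Returns -sign(slope) * R^2, or NaN when fewer than two
    non-empty bins remain.
    """
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.ptp(np.log10(k)) == 0:
        return float("nan")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 2:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def soft_threshold_scan(
    expr: pd.DataFrame,
    powers=tuple(range(1, 21)),
    r2_threshold: float = 0.9,
) -> pd.DataFrame:
    """Scan soft-threshold powers for scale-free topology.

    Returns a table indexed by beta with columns ``signed_r2`` and
    ``mean_connectivity``, plus attribute-style access to the chosen beta via
    :func:`choose_beta`.
    """
    if expr.shape[0] < 30:
        warnings.warn("fewer than 30 genes: scale-free fit is unreliable", stacklevel=2)
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    rows = []
    for beta in powers:
        adj = abs_corr**beta
        k = adj.sum(axis=1)
        rows.append((int(beta), scale_free_fit(k), float(k.mean())))
    return pd.DataFrame(rows, columns=["beta", "signed_r2", "mean_connectivity"]).set_index("beta")


def choose_beta(scan: pd.DataFrame, r2_threshold: float = 0.9) -> int | None:
    """Smallest beta whose signed R^2 reaches the threshold, or None."""
    hits = scan.index[scan["signed_r2"] >= r2_threshold]
    return int(hits[0]) if len(hits) else None


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j, and TOM_ii = 1. Input must be
    symmetric with entries in [0, 1]; the diagonal is ignored.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diag(a)=0 so u=i,j terms vanish
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    gene_ids,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cut the TOM dendrogram into modules and compute eigengenes.

    Average-linkage clustering on dissimilarity 1 - TOM with a flat cut at
    ``cut_height``; clusters below ``min_module_size`` fall into "grey".
    Color labels are assigned by decreasing module size. The eigengene of a
    module is the first principal component of its standardized expression,
    scaled to unit variance and oriented to correlate positively with the
    module's mean expression profile.

    Returns ``(labels, eigengenes)``: a gene-indexed Series of module colors
    and a samples x modules eigengene DataFrame (columns ``ME<color>``).
    """
    gene_ids = pd.Index(gene_ids)
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene ids")
    # canonical gene order so the partition is independent of input order
    order = np.argsort(gene_ids)
    inv = np.argsort(order)
    diss = 1.0 - tom[np.ix_(order, order)]
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(diss, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")[inv]

    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], c))
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(kept)}
    labels = pd.Series(
        [color_of.get(c, UNASSIGNED) for c in raw], index=gene_ids, name="module"
    )

    if not kept:
        warnings.warn("all genes unassigned (grey); no eigengenes", stacklevel=2)
        return labels, pd.DataFrame(index=expr.columns)

    eigengenes = {}
    for c in kept:
        color = color_of[c]
        sub = expr.loc[labels.index[labels == color]].to_numpy(dtype=float)
        eigengenes[f"ME{color}"] = module_eigengene(sub)
    return labels, pd.DataFrame(eigengenes, index=expr.columns)


def module_eigengene(module_expr: np.ndarray) -> np.ndarray:
    """First PC of standardized module expression (genes x samples).

    Unit variance, oriented to correlate positively with the module mean
    expression profile.
    """
    x = np.asarray(module_expr, dtype=float)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    # PC over samples: right singular vector of the genes x samples matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_profile = x.mean(axis=0)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    return pc / pc.std(ddof=0)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    r_threshold: float = 0.35,
    p_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Binary traits must be coded 0/1. Two-sided p-values use the
    t-distribution with n - 2 degrees of freedom. Modules with
    r > ``r_threshold`` and p < ``p_threshold`` are flagged as
    trait-associated. Zero-variance traits yield missing r and p.
    """
    rows = []
    for me in eigengenes.columns:
        e = eigengenes[me].to_numpy(dtype=float)
        for trait in traits.columns:
            t_vals = traits[trait].to_numpy(dtype=float)
            mask = ~np.isnan(t_vals)
            if mask.sum() < 3 or np.ptp(t_vals[mask]) == 0:
                rows.append((me, trait, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(e[mask], t_vals[mask])
            rows.append((me, trait, float(r), float(p),
                         bool(r > r_threshold and p < p_threshold)))
    return pd.DataFrame(rows, columns=["module", "trait", "pearson_r", "p_value", "associated"])


class CoexpressionNetwork(BaseEstimator):
    """WGCNA-style coexpression screening as an estimator.

    Fit on a samples x genes DataFrame (sklearn orientation). The fitted
    object exposes the soft-threshold scan, the selected beta, per-gene
    module labels and the module eigengenes.

    Parameters
    ----------
    powers : sequence of int, default 1..20
        Candidate soft-threshold powers.
    r2_threshold : float, default 0.9
        Scale-free fit index required to accept a power.
    beta : int or None
        Fixed power; overrides the scan when set.
    fallback_beta : int, default 6
        Power used when no candidate reaches ``r2_threshold``.
    min_module_size : int, default 30
    cut_height : float, default 0.99
        Static cut height on the 1 - TOM dendrogram.
    variance_quantile : float or None, default None
        When set, restrict to the top fraction of genes by variance first.
    """

    def __init__(self, powers=tuple(range(1, 21)), r2_threshold: float = 0.9,
                 beta: int | None = None, fallback_beta: int = 6,
                 min_module_size: int = 30, cut_height: float = 0.99,
                 variance_quantile: float | None = None):
        self.powers = powers
        self.r2_threshold = r2_threshold
        self.beta = beta
        self.fallback_beta = fallback_beta
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.variance_quantile = variance_quantile

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x genes DataFrame")
        expr = X.T  # genes x samples
        if self.variance_quantile is not None:
            expr = variance_filter(expr, self.variance_quantile)
        self.gene_ids_ = expr.index
        self.scan_ = soft_threshold_scan(expr, self.powers, self.r2_threshold)
        if self.beta is not None:
            self.beta_ = int(self.beta)
        else:
            chosen = choose_beta(self.scan_, self.r2_threshold)
            self.beta_ = chosen if chosen is not None else int(self.fallback_beta)
            self.beta_from_scan_ = chosen is not None
        adj = adjacency_matrix(expr, self.beta_)
        self.tom_ = tom_similarity(adj)
        self.labels_, self.eigengenes_ = detect_modules(
            self.tom_, expr.index, expr, self.min_module_size, self.cut_height
        )
        return self

    def trait_correlation(self, traits: pd.DataFrame, r_threshold: float = 0.35,
                          p_threshold: float = 1e-3) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "eigengenes_")
        traits = traits.loc[self.eigengenes_.index]
        return module_trait_correlation(self.eigengenes_, traits, r_threshold, p_threshold)
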