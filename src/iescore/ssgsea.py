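"""Single-sample gene set enrichment analysis (ssGSEA).

For one sample, genes are ranked by expression (rank 1 = highest, ties
broken by gene id so scoring is deterministic) and each gene receives the
descending-rank weight ``r = N - rank + 1``. Walking the ranked list from
the top, the enrichment score of a set S is the summed gap between the
weighted in-set ECDF and the uniform out-of-set ECDF::

    P_in(i)  = sum_{g in S, rank_g <= i} r_g^tau / sum_{g in S} r_g^tau
    P_out(i) = |{g not in S, rank_g <= i}| / (N - |S|)
    ES       = sum_{i=1..N} (P_in(i) - P_out(i))

``tau`` (default 0.25) controls how sharply the top of the ranking is
weighted; ``tau = 0`` gives uniform in-set steps. Scores are optionally
normalized by the global range of the score matrix, the convention used
when scores from sets of different sizes are compared or fed to PCA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def rank_genes(expr: pd.DataFrame, sample: str) -> pd.Series:
    """Rank genes of one sample, 1 = highest expression, ties by gene id."""
    if sample not in expr.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    order = _rank_order(expr[sample].to_numpy(), expr.index.to_numpy())
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return pd.Series(ranks, index=expr.index, name=sample)


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices of genes in rank order (descending value, ascending id on ties)."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -values))


def _es_from_order(in_set_ordered: np.ndarray, tau: float) -> float:
    n = in_set_ordered.shape[0]
    n_set = int(in_set_ordered.sum())
    if n_set == 0:
        raise ValueError("no genes of the set are present in the matrix")
    if n_set == n:
        raise ValueError("gene set spans the whole matrix; out-of-set part is empty")
    weights = (np.arange(n, 0, -1, dtype=float)) ** tau  # weight of rank i is (N-i+1)^tau
    w_in = np.where(in_set_ordered, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set_ordered) / (n - n_set)
    return float(np.sum(p_in - p_out))


def ssgsea_score(expr: pd.DataFrame, gene_set: list[str], sample: str, tau: float = 0.25) -> float:
    """Unnormalized ssGSEA enrichment score of one gene set in one sample.

    Genes of the set absent from the matrix are ignored. ``tau`` must be
    non-negative.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if sample not in expr.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    present = set(gene_set) & set(expr.index)
    if not present:
        raise ValueError(f"no genes of the set present in the matrix: {gene_set[:5]}...")
    order = _rank_order(expr[sample].to_numpy(), expr.index.to_numpy())
    in_set = np.asarray(expr.index.isin(present))
    return _es_from_order(in_set[order], tau)


def score_all(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    tau: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores for every (sample, gene set) pair.

    Returns a samples x signatures DataFrame. When ``normalize`` is true all
    entries are divided by the global (max - min) of the raw score matrix.
    """
    scorer = SSGSEAScorer(gene_sets=sets, tau=tau, normalize=normalize)
    return scorer.fit_transform_expression(expr)


class SSGSEAScorer(BaseEstimator, TransformerMixin):
    """ssGSEA scoring as a scikit-learn transformer.

    ``X`` follows the sklearn layout (samples x genes); feature names carry
    the gene ids, so fitting requires a DataFrame (or ``feature_names`` set
    explicitly). :meth:`fit_transform_expression` accepts the field's
    genes x samples orientation directly.

    Parameters
    ----------
    gene_sets : dict[str, list[str]]
        Named gene sets to score.
    tau : float, default 0.25
        Rank-weight exponent.
    normalize : bool, default True
        Divide scores by the global range of the score matrix.
    """

    def __init__(self, gene_sets: dict[str, list[str]] | None = None, tau: float = 0.25,
                 normalize: bool = True):
        self.gene_sets = gene_sets
        self.tau = tau
        self.normalize = normalize

    def fit(self, X, y=None):
        if not self.gene_sets:
            raise ValueError("gene_sets must be a non-empty mapping")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        X = self._as_frame(X)
        genes = set(X.columns)
        self.present_genes_: dict[str, list[str]] = {}
        for name, members in self.gene_sets.items():
            present = [g for g in dict.fromkeys(members) if g in genes]
            if not present:
                raise ValueError(f"gene set {name!r} has no genes in the matrix")
            dropped = len(set(members)) - len(present)
            if dropped:
                logger.info("gene set %s: %d genes absent from the matrix", name, dropped)
            if len(present) == X.shape[1]:
                raise ValueError(f"gene set {name!r} covers every gene; score undefined")
            self.present_genes_[name] = present
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "present_genes_")
        X = self._as_frame(X)
        gene_ids = X.columns.to_numpy().astype(str)
        values = X.to_numpy(dtype=float)
        n_samples, n_genes = values.shape
        weights_by_rank = (np.arange(n_genes, 0, -1, dtype=float)) ** self.tau
        masks = {name: np.asarray(X.columns.isin(genes))
                 for name, genes in self.present_genes_.items()}
        scores = np.empty((n_samples, len(masks)))
        for j in range(n_samples):
            order = _rank_order(values[j], gene_ids)
            for k, (name, mask) in enumerate(masks.items()):
                m = mask[order]
                w_in = np.where(m, weights_by_rank, 0.0)
                p_in = np.cumsum(w_in) / w_in.sum()
                p_out = np.cumsum(~m) / (n_genes - m.sum())
                scores[j, k] = np.sum(p_in - p_out)
        out = pd.DataFrame(scores, index=X.index, columns=list(masks))
        if self.normalize:
            rng = out.to_numpy().max() - out.to_numpy().min()
            if rng > 0:
                out = out / rng
        return out

    def fit_transform_expression(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Score a genes x samples expression matrix (field orientation)."""
        X = expr.T
        return self.fit(X).transform(X)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError("SSGSEAScorer requires a DataFrame whose columns are gene ids")
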