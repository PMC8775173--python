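"""Immune Effective Score (IES).

The IES of a sample is the sum of the first two principal components of its
seven immune signature ssGSEA scores (CD8 T cells, Tfh, Th1, NK, cytolytic
activity, inflammation promoting, T-cell costimulation). Components are
sign-oriented so that each component's loadings sum to a non-negative value,
making "high IES" mean coordinated elevation of the immune signatures.
Samples with IES at or above the upper-tertile cutoff are labeled "high".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

#: the seven immune effector signatures the score is built from
DEFAULT_SIGNATURES = (
    "CD8_T_cells",
    "Tfh",
    "Th1",
    "NK",
    "Cytolytic_activity",
    "Inflammation_promoting",
    "T_cell_costimulation",
)


class ImmuneEffectiveScore(BaseEstimator, TransformerMixin):
    """PCA-based composite immune score, fitted per cohort.

    Parameters
    ----------
    standardize : bool, default True
        Center and scale each signature column to unit variance before PCA
        (correlation-matrix PCA). ssGSEA scores from sets of different sizes
        live on different scales, so this is the default.
    signatures : sequence of str or None
        Required signature columns. ``None`` accepts any >= 2 columns;
        the default pipeline passes the seven immune signatures.

    Attributes
    ----------
    loadings_ : DataFrame (n_signatures x 2)
        Sign-oriented loadings of the first two components.
    explained_variance_ratio_ : ndarray of shape (2,)
    pc_scores_ : DataFrame (n_samples x 2), columns PC1/PC2
    ies_ : Series, per-sample IES = PC1 + PC2
    cutoff_ : float, the upper-tertile cutoff applied to ``ies_``
    groups_ : Series of {"high", "low"}
    """

    def __init__(self, standardize: bool = True, signatures=DEFAULT_SIGNATURES):
        self.standardize = standardize
        self.signatures = signatures

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        values = X.to_numpy(dtype=float)
        mean = values.mean(axis=0)
        scale = values.std(axis=0, ddof=1)
        if self.standardize:
            if np.any(scale == 0):
                bad = list(X.columns[scale == 0])
                raise ValueError(f"constant signature columns cannot be standardized: {bad}")
            values = (values - mean) / scale
        else:
            values = values - mean
        pca = PCA(n_components=2, svd_solver="full")
        scores = pca.fit_transform(values)
        loadings = pca.components_.T.copy()  # signatures x 2
        for k in range(2):
            s = loadings[:, k].sum()
            flip = s < 0 or (s == 0 and loadings[0, k] < 0)
            if flip:
                loadings[:, k] *= -1
                scores[:, k] *= -1
        self.mean_ = mean
        self.scale_ = scale if self.standardize else np.ones_like(scale)
        self.loadings_ = pd.DataFrame(loadings, index=X.columns, columns=["PC1", "PC2"])
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:2]
        self.pc_scores_ = pd.DataFrame(scores, index=X.index, columns=["PC1", "PC2"])
        self.ies_ = self.pc_scores_.sum(axis=1).rename("ies")
        self.groups_, self.cutoff_ = assign_groups(self.ies_)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project signature scores onto the fitted components (PC1, PC2, IES)."""
        check_is_fitted(self, "loadings_")
        X = self._validate(X)
        values = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        pcs = values @ self.loadings_.to_numpy()
        out = pd.DataFrame(pcs, index=X.index, columns=["PC1", "PC2"])
        out["ies"] = out["PC1"] + out["PC2"]
        return out

    def result_table(self) -> pd.DataFrame:
        """Per-sample table: PC1, PC2, IES, group."""
        check_is_fitted(self, "ies_")
        table = self.pc_scores_.copy()
        table["ies"] = self.ies_
        table["group"] = self.groups_
        return table

    def _validate(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x signatures DataFrame")
        if self.signatures is not None:
            missing = [s for s in self.signatures if s not in X.columns]
            if missing:
                raise ValueError(f"missing signature columns: {missing}")
            X = X[list(self.signatures)]
        if X.shape[1] < 2:
            raise ValueError("need at least 2 signature columns")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        return X


def build_ies(scores: pd.DataFrame, standardize: bool = True,
              signatures=DEFAULT_SIGNATURES) -> ImmuneEffectiveScore:
    """Fit an :class:`ImmuneEffectiveScore` on a samples x signatures table."""
    return ImmuneEffectiveScore(standardize=standardize, signatures=signatures).fit(scores)


def assign_groups(ies: pd.Series | np.ndarray) -> tuple[pd.Series, float]:
    """Label the top one-third of IES values "high", the rest "low".

    The cutoff is the 2/3 quantile with linear (type-7) interpolation;
    samples with IES >= cutoff are "high", so ties at the cutoff all go
    high and tie-free inputs yield exactly ceil(n/3) high samples.
    """
    values = np.asarray(ies, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 samples to form tertiles")
    if np.ptp(values) == 0:
        raise ValueError("degenerate score: all IES values identical")
    cutoff = float(np.quantile(values, 2.0 / 3.0, method="linear"))
    labels = np.where(values >= cutoff, "high", "low")
    index = ies.index if isinstance(ies, pd.Series) else pd.RangeIndex(values.size)
    return pd.Series(labels, index=index, name="group"), cutoff


def correlate_with_infiltration(ies: pd.Series, infiltration: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of IES with each infiltration score column.

    Returns a table with tie-corrected Spearman rho, two-sided p (t
    approximation) and Benjamini-Hochberg q-values.
    """
    if not ies.index.equals(infiltration.index):
        if set(ies.index) != set(infiltration.index):
            raise ValueError("IES and infiltration tables cover different samples")
        infiltration = infiltration.loc[ies.index]
    if len(ies) < 4:
        raise ValueError("need at least 4 samples for a stable Spearman p-value")
    rows = []
    for col in infiltration.columns:
        rho, p = stats.spearmanr(ies.to_numpy(), infiltration[col].to_numpy())
        rows.append((col, float(rho), float(p)))
    table = pd.DataFrame(rows, columns=["cell_type", "spearman_rho", "p_value"])
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
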