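"""Prognostic evaluation: Kaplan-Meier, log-rank, and Cox regression.

Kaplan-Meier curves and the two-group log-rank test are delegated to
lifelines; Greenwood standard errors are computed from the per-group event
tables. The Cox proportional hazards model is fitted here by Newton-Raphson
on the partial likelihood with a choice of Efron (default) or Breslow tie
handling, so that both conventions are available under one switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

Z975 = 1.959963984540054


@dataclass
class SurvivalFit:
    """Per-group Kaplan-Meier estimates plus the log-rank comparison."""

    groups: list[str]
    tables: dict[str, pd.DataFrame]  # per-group: time, at_risk, events, survival, greenwood_se
    logrank_chi2: float
    logrank_p: float


def km_fit(time, event, group) -> SurvivalFit:
    """Kaplan-Meier product-limit fit per group with a log-rank test.

    Censored observations tied with events at the same time are counted at
    risk for those events (censoring-after-events convention). Requires at
    least one event overall.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time < 0).any():
        raise ValueError("negative survival times")
    if event.sum() == 0:
        raise ValueError("no events: survival comparison undefined")
    if time[event == 1].max() == 0 and time.max() == 0:
        raise ValueError("degenerate times: all observations at t=0")

    labels = [str(g) for g in pd.unique(group)]
    tables = {}
    for g in labels:
        mask = group.astype(str) == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        ev = kmf.event_table
        # Greenwood: var(S(t)) = S(t)^2 * cumsum(d / (n (n - d)))
        d = ev["observed"].to_numpy(dtype=float)
        n_risk = ev["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.nan)
        surv = kmf.survival_function_["KM_estimate"].to_numpy()
        se = surv * np.sqrt(np.nancumsum(inc))
        tables[g] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": n_risk.astype(int),
                "events": d.astype(int),
                "survival": surv,
                "greenwood_se": se,
            }
        ).reset_index(drop=True)

    if len(labels) >= 2:
        lr = multivariate_logrank_test(time, group.astype(str), event)
        chi2, p = float(lr.test_statistic), float(lr.p_value)
    else:
        chi2, p = float("nan"), float("nan")
    return SurvivalFit(labels, tables, chi2, p)


@dataclass
class CoxResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (p, 2)
    wald_p: np.ndarray
    n_events: int
    converged: bool
    n_iter: int
    loglik: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_lower95": self.ci95[:, 0],
                "hr_upper95": self.ci95[:, 1],
                "wald_p": self.wald_p,
            },
            index=self.terms,
        )


class CoxPH(BaseEstimator):
    """Cox proportional hazards model via Newton-Raphson.

    Maximizes the partial likelihood with Efron (default) or Breslow
    handling of tied event times. Convergence when the largest score
    component falls below ``tol`` (default 1e-9) or after ``max_iter``
    Newton steps (with step-halving on likelihood decrease). Covariates are
    centered internally for numerical stability; coefficients are unchanged
    by centering.

    Fit with ``fit(X, y)`` where ``X`` is a samples x covariates DataFrame
    (categorical columns are expanded to reference-coded indicators) and
    ``y`` is a 2-column array-like of (time, event).
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-9, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        X = self._design(X)
        y = np.asarray(y, dtype=float)
        time, event = y[:, 0], y[:, 1].astype(int)
        if (time < 0).any():
            raise ValueError("negative survival times")
        if not set(np.unique(event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        Z = X.to_numpy(dtype=float)
        if np.any(Z.std(axis=0) == 0):
            bad = list(X.columns[Z.std(axis=0) == 0])
            raise ValueError(f"constant covariate(s): {bad}")
        n_events = int(event.sum())
        if n_events < 1:
            raise ValueError("no events")
        if n_events < Z.shape[1]:
            warnings.warn(
                f"{n_events} events for {Z.shape[1]} covariates: estimates unstable",
                stacklevel=2,
            )
        center = Z.mean(axis=0)
        Zc = Z - center

        beta, loglik, converged, n_iter = _newton_raphson(
            Zc, time, event, ties=self.ties, tol=self.tol, max_iter=self.max_iter
        )
        info = -_loglik_derivs(beta, Zc, time, event, self.ties)[2]
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        if np.any(np.abs(beta) > 20):
            warnings.warn("possible separation: |coef| > 20", stacklevel=2)
        z = beta / se
        wald_p = 2 * stats.norm.sf(np.abs(z))
        ci = np.column_stack([np.exp(beta - Z975 * se), np.exp(beta + Z975 * se)])

        self.result_ = CoxResult(
            terms=list(X.columns),
            coef=beta,
            se=se,
            hr=np.exp(beta),
            ci95=ci,
            wald_p=wald_p,
            n_events=n_events,
            converged=converged,
            n_iter=n_iter,
            loglik=loglik,
        )
        self.coef_ = beta
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new covariates."""
        X = self._design(X)
        X = X.reindex(columns=self.feature_names_in_, fill_value=0.0)
        return X.to_numpy(dtype=float) @ self.coef_

    @staticmethod
    def _design(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        cat = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
        if cat:
            X = pd.get_dummies(X, columns=cat, drop_first=True, dtype=float)
        return X.astype(float)


def cox_fit(time, event, covariates: pd.DataFrame, ties: str = "efron") -> CoxResult:
    """Convenience wrapper around :class:`CoxPH`."""
    y = np.column_stack([np.asarray(time, dtype=float), np.asarray(event, dtype=float)])
    return CoxPH(ties=ties).fit(covariates, y).result_


def _loglik_derivs(beta, Z, time, event, ties):
    """Partial log-likelihood, score vector and Hessian (Efron or Breslow)."""
    n, p = Z.shape
    order = np.argsort(-time, kind="stable")  # decreasing time for running risk sums
    Zs, ts, es = Z[order], time[order], event[order]
    eta = Zs @ beta
    w = np.exp(eta)
    wZ = Zs * w[:, None]
    wZZ = np.einsum("i,ij,ik->ijk", w, Zs, Zs)

    loglik = 0.0
    score = np.zeros(p)
    hess = np.zeros((p, p))

    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # everyone with time >= ts[i] enters the risk set
        s0 += w[i:j].sum()
        s1 += wZ[i:j].sum(axis=0)
        s2 += wZZ[i:j].sum(axis=0)
        ev = np.nonzero(es[i:j])[0] + i
        d = len(ev)
        if d:
            zsum = Zs[ev].sum(axis=0)
            loglik += eta[ev].sum()
            if ties == "breslow":
                loglik -= d * np.log(s0)
                score += zsum - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
            else:  # efron
                d0 = w[ev].sum()
                d1 = wZ[ev].sum(axis=0)
                d2 = wZZ[ev].sum(axis=0)
                for r in range(d):
                    f = r / d
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    loglik -= np.log(a0)
                    score -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1, a1) / a0**2
                score += zsum
        i = j
    return loglik, score, hess


def _newton_raphson(Z, time, event, ties, tol, max_iter):
    p = Z.shape[1]
    beta = np.zeros(p)
    loglik, score, hess = _loglik_derivs(beta, Z, time, event, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_score, new_hess = _loglik_derivs(new_beta, Z, time, event, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_hess = _loglik_derivs(new_beta, Z, time, event, ties)
            halvings += 1
        beta, loglik, score, hess = new_beta, new_ll, new_score, new_hess
    else:
        converged = np.max(np.abs(score)) < tol
    if np.max(np.abs(score)) < tol:
        converged = True
    return beta, loglik, converged, it


@dataclass
class PrognosticReport:
    endpoint: str
    km: SurvivalFit
    multivariate: CoxResult
    univariate: dict[str, CoxResult] = field(default_factory=dict)

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot-ready table with BH-adjusted multivariate p-values."""
        tab = self.multivariate.summary().copy()
        tab["q_value"] = multipletests(tab["wald_p"], method="fdr_bh")[1]
        uni = {t: r.summary().loc[t] for t, r in self.univariate.items() if t in r.terms}
        if uni:
            u = pd.DataFrame(uni).T
            tab["hr_univariate"] = u["hr"]
            tab["p_univariate"] = u["wald_p"]
        return tab


def prognostic_report(
    ies: pd.Series,
    groups: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "OS",
    covariates: list[str] | None = None,
    standardize_ies: bool = True,
    ties: str = "efron",
) -> PrognosticReport:
    """Kaplan-Meier by IES group plus multivariate and univariate Cox.

    ``endpoint`` selects the (os_time, os_event) or (pfi_time, pfi_event)
    columns. The IES enters the Cox model continuously, by default scaled to
    unit variance so hazard ratios read per standard deviation.
    """
    endpoint = endpoint.upper()
    time_col, event_col = {
        "OS": ("os_time", "os_event"),
        "PFI": ("pfi_time", "pfi_event"),
    }[endpoint]
    for col in (time_col, event_col):
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
    keep = clinical[[time_col, event_col]].notna().all(axis=1)
    samples = clinical.index[keep].intersection(ies.index)
    time = clinical.loc[samples, time_col].to_numpy(dtype=float)
    event = clinical.loc[samples, event_col].to_numpy(dtype=int)
    if event.sum() and time[event == 1].max() == 0:
        raise ValueError("degenerate times: every event at t=0")

    km = km_fit(time, event, groups.loc[samples].to_numpy())

    x = ies.loc[samples].astype(float)
    if standardize_ies:
        x = (x - x.mean()) / x.std(ddof=1)
    design = pd.DataFrame({"ies": x})
    covariates = [c for c in (covariates or []) if c in clinical.columns]
    for c in covariates:
        design[c] = clinical.loc[samples, c]
    design = design.dropna()
    aligned = design.index
    y = np.column_stack(
        [clinical.loc[aligned, time_col].to_numpy(dtype=float),
         clinical.loc[aligned, event_col].to_numpy(dtype=float)]
    )
    multi = CoxPH(ties=ties).fit(design, y).result_
    uni = {}
    for col in design.columns:
        res = CoxPH(ties=ties).fit(design[[col]], y).result_
        for term in res.terms:
            uni[term] = res
    return PrognosticReport(endpoint, km, multi, uni)
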