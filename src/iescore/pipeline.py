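"""End-to-end IES pipeline: score, stratify, screen, evaluate, report.

Orchestrates the full analysis on one cohort: align expression and clinical
samples, ssGSEA-score the seven immune signatures, build the IES and tertile
groups, run the coexpression module/trait screen, evaluate pCR prediction
(rates, Fisher, ROC/AUC) and prognosis (KM, log-rank, Cox), and write TSV
tables plus a machine-readable JSON report. Deterministic given inputs and
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr as cx
from . import io as iio
from . import predict as pr
from . import survival as sv
from .ies import DEFAULT_SIGNATURES, ImmuneEffectiveScore, correlate_with_infiltration
from .ssgsea import SSGSEAScorer

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline."""

    tau: float = 0.25                      # ssGSEA rank-weight exponent
    normalize_scores: bool = True          # divide scores by the global range
    standardize_signatures: bool = True    # correlation-PCA for the IES
    log2_transform: bool = False           # apply log2(x+1) to raw inputs
    variance_quantile: float = 0.25        # coexpression gene filter
    powers: tuple = tuple(range(1, 21))    # soft-threshold candidates
    r2_threshold: float = 0.9              # scale-free fit acceptance
    fallback_beta: int = 6
    min_module_size: int = 30
    cut_height: float = 0.99
    module_r_threshold: float = 0.35
    module_p_threshold: float = 1e-3
    run_coexpression: bool = True
    covariates: tuple = ("age", "stage")   # Cox adjustment terms when present
    standardize_ies: bool = True           # per-SD hazard ratios
    cox_ties: str = "efron"
    endpoints: tuple = ("OS", "PFI")
    seed: int = 0

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not 0 < self.variance_quantile < 1:
            raise ValueError("variance_quantile must be in (0, 1)")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if any(int(p) <= 0 for p in self.powers):
            raise ValueError("powers must be positive integers")


def run_pipeline(
    config: PipelineConfig,
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    clinical: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis; return (and optionally write) the report bundle."""
    expr, clinical = iio.align_samples(expr, clinical)
    if config.log2_transform:
        expr = np.log2(expr + 1.0)

    report: dict = {"config": _jsonable(asdict(config)), "n_samples": int(expr.shape[1]),
                    "n_genes": int(expr.shape[0])}
    tables: dict[str, pd.DataFrame] = {}

    # --- signature scoring and IES -------------------------------------
    sig_sets = {name: sets[name] for name in DEFAULT_SIGNATURES if name in sets}
    if len(sig_sets) < 7:
        missing = sorted(set(DEFAULT_SIGNATURES) - set(sig_sets))
        raise ValueError(f"gene set collection lacks signatures: {missing}")
    scorer = SSGSEAScorer(gene_sets=sig_sets, tau=config.tau,
                          normalize=config.normalize_scores)
    scores = scorer.fit_transform_expression(expr)
    tables["signature_scores"] = scores

    model = ImmuneEffectiveScore(standardize=config.standardize_signatures).fit(scores)
    ies_table = model.result_table()
    tables["ies"] = ies_table
    report["ies"] = {
        "cutoff": model.cutoff_,
        "n_high": int((model.groups_ == "high").sum()),
        "n_low": int((model.groups_ == "low").sum()),
        "explained_variance_ratio": [float(v) for v in model.explained_variance_ratio_],
        "loadings": {c: {s: float(v) for s, v in model.loadings_[c].items()}
                     for c in model.loadings_.columns},
    }

    # correlation of the IES with any extra (infiltration-style) gene sets
    extra = {k: v for k, v in sets.items() if k not in DEFAULT_SIGNATURES}
    if extra and len(scores) >= 4:
        try:
            infil = SSGSEAScorer(gene_sets=extra, tau=config.tau,
                                 normalize=config.normalize_scores
                                 ).fit_transform_expression(expr)
            corr = correlate_with_infiltration(model.ies_, infil)
            tables["ies_infiltration_correlation"] = corr.set_index("cell_type")
            report["infiltration_correlation"] = corr.to_dict(orient="records")
        except ValueError as exc:
            logger.warning("infiltration correlation skipped: %s", exc)

    # --- coexpression screen -------------------------------------------
    if config.run_coexpression:
        net = cx.CoexpressionNetwork(
            powers=config.powers, r2_threshold=config.r2_threshold,
            fallback_beta=config.fallback_beta,
            min_module_size=config.min_module_size, cut_height=config.cut_height,
            variance_quantile=config.variance_quantile,
        ).fit(expr.T)
        tables["soft_threshold_scan"] = net.scan_
        tables["gene_modules"] = net.labels_.to_frame()
        tables["module_eigengenes"] = net.eigengenes_
        report["coexpression"] = {
            "chosen_beta": net.beta_,
            "beta_from_scan": bool(getattr(net, "beta_from_scan_", True)),
            "n_modules": int(net.eigengenes_.shape[1]),
            "module_sizes": {m: int(c) for m, c in
                             net.labels_.value_counts().items()},
        }
        traits = {}
        if "response" in clinical.columns:
            resp = clinical["response"]
            traits["pcr"] = resp.map({"pCR": 1.0, "RD": 0.0})
        traits["ies_high"] = (model.groups_ == "high").astype(float)
        if traits and net.eigengenes_.shape[1]:
            trait_df = pd.DataFrame(traits, index=clinical.index)
            mt = net.trait_correlation(trait_df, config.module_r_threshold,
                                       config.module_p_threshold)
            tables["module_trait"] = mt
            report["coexpression"]["trait_associated_modules"] = sorted(
                mt.loc[mt["associated"], "module"].unique().tolist()
            )

    # --- predictive evaluation -----------------------------------------
    has_response = "response" in clinical.columns and clinical["response"].isin(
        ["pCR", "RD"]).sum() >= 4
    if has_response:
        resp = clinical["response"]
        rt = pr.response_table(model.groups_, resp)
        mask = resp.isin(["pCR", "RD"])
        roc = pr.roc_auc(model.ies_[mask].to_numpy(),
                         (resp[mask] == "pCR").astype(int).to_numpy())
        tables["roc_points"] = roc.roc_points
        report["predictive"] = {
            "counts": {g: {r: int(rt.counts.loc[g, r]) for r in rt.counts.columns}
                       for g in rt.counts.index},
            "pcr_rate_high": rt.pcr_rate_high,
            "pcr_rate_low": rt.pcr_rate_low,
            "fisher_p": rt.fisher_p,
            "auc": roc.auc,
            "auc_ci95": [roc.auc_ci[0], roc.auc_ci[1]],
            "n_excluded": rt.n_excluded,
        }
    else:
        report["predictive"] = {"status": "skipped", "reason": "no usable response data"}

    # --- prognostic evaluation ------------------------------------------
    report["survival"] = {}
    for endpoint in config.endpoints:
        cols = {"OS": ("os_time", "os_event"), "PFI": ("pfi_time", "pfi_event")}[endpoint]
        if not all(c in clinical.columns for c in cols):
            report["survival"][endpoint] = {"status": "skipped",
                                            "reason": f"missing columns {cols}"}
            continue
        try:
            prog = sv.prognostic_report(
                model.ies_, model.groups_, clinical, endpoint=endpoint,
                covariates=list(config.covariates),
                standardize_ies=config.standardize_ies, ties=config.cox_ties,
            )
        except ValueError as exc:
            report["survival"][endpoint] = {"status": "skipped", "reason": str(exc)}
            continue
        forest = prog.forest_table()
        tables[f"cox_{endpoint.lower()}"] = forest
        for g, t in prog.km.tables.items():
            tables[f"km_{endpoint.lower()}_{g}"] = t
        report["survival"][endpoint] = {
            "logrank_chi2": prog.km.logrank_chi2,
            "logrank_p": prog.km.logrank_p,
            "cox": {
                term: {
                    "hr": float(prog.multivariate.hr[i]),
                    "ci95": [float(prog.multivariate.ci95[i, 0]),
                             float(prog.multivariate.ci95[i, 1])],
                    "p": float(prog.multivariate.wald_p[i]),
                }
                for i, term in enumerate(prog.multivariate.terms)
            },
            "n_events": prog.multivariate.n_events,
            "converged": prog.multivariate.converged,
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t")
        (out / "report.json").write_text(report_json(report))
    report["_tables"] = tables
    return report


def report_json(report: dict) -> str:
    """Serialize the report deterministically (sorted keys, fixed floats)."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(_jsonable(clean), sort_keys=True, indent=2) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
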