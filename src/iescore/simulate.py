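"""Synthetic HER2+ cohort generator.

Emulates the statistical structure the IES analysis assumes: a latent
per-sample immune-infiltration factor z ~ N(0,1) that (a) elevates the
expression of genes in seven immune effector gene sets, (b) raises the
probability of pathological complete response through a logistic link, and
(c) lowers the event hazard through a proportional-hazards link; plus
block-correlated "module" genes driven by shared factors for the
coexpression stage, one of which also feeds the response, and independent
background genes. Expression is generated directly on the log-intensity
scale.

Default sizes and effects mirror a mid-sized neoadjuvant cohort: n = 123
samples, 2000 genes, seven disjoint 40-gene signatures with loading 0.8 on
z against unit noise, five 50-gene modules with factor SD 2 (within-module
correlation about 0.8), a baseline pCR rate near 30%, and an exponential
hazard calibrated with uniform censoring to roughly 40% observed events.
The hazard loading defaults to -ln(0.66), i.e. a protective hazard ratio of
0.66 per SD of the latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .ies import DEFAULT_SIGNATURES


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator."""

    n_samples: int = 123
    n_genes: int = 2000
    n_signature_genes: int = 40          # genes per immune set (7 sets)
    signature_overlap: float = 0.0       # fraction of each set shared with the next
    loading: float = 0.8                 # lambda: signature-gene load on latent z
    noise_sd: float = 1.0                # sigma
    n_modules: int = 5
    module_size: int = 50
    module_factor_sd: float = 2.0        # within-module r = s^2/(s^2+sigma^2) = 0.8
    gamma_mod: float = 1.0               # module-1 factor weight in the pCR link
    alpha: float = -0.85                 # pCR intercept (baseline rate ~ 30%)
    gamma: float = 1.0                   # pCR slope on z
    h0: float = 0.01                     # baseline hazard per month
    delta: float = 0.4155                # protective hazard loading, ~ -ln(0.66)
    pfi_rate_ratio: float = 1.5          # PFI hazard relative to OS
    censor_max: float = 120.0            # uniform censoring window (months)
    weibull_shape: float | None = None   # None = exponential baseline
    mean_expression: float = 6.0
    mean_expression_sd: float = 1.0
    seed: int = 0


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used only by tests."""

    expr: pd.DataFrame                 # genes x samples, log scale
    sets: dict[str, list[str]]         # 7 immune sets + module ground truth sets
    clinical: pd.DataFrame             # sample-indexed
    latent: pd.Series                  # z, never consumed by the pipeline
    module_labels: pd.Series           # ground-truth gene -> module map
    module_factors: pd.DataFrame = field(default=None)
    config: GeneratorConfig = field(default=None)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one synthetic cohort. Fully determined by ``config`` (incl. seed)."""
    c = config
    n_sig = 7 * c.n_signature_genes
    n_mod = c.n_modules * c.module_size
    if n_sig + n_mod > c.n_genes:
        raise ValueError(
            f"gene budget exceeded: {n_sig} signature + {n_mod} module genes "
            f"> {c.n_genes} total"
        )
    rng = np.random.default_rng(c.seed)
    genes = np.array([f"G{i:05d}" for i in range(c.n_genes)])
    samples = np.array([f"S{j:03d}" for j in range(c.n_samples)])

    z = rng.standard_normal(c.n_samples)
    mu = rng.normal(c.mean_expression, c.mean_expression_sd, size=c.n_genes)
    X = mu[:, None] + rng.normal(0.0, c.noise_sd, size=(c.n_genes, c.n_samples))

    # immune signature sets: contiguous, optionally overlapping blocks
    step = max(1, int(round(c.n_signature_genes * (1.0 - c.signature_overlap))))
    sets: dict[str, list[str]] = {}
    sig_members: set[int] = set()
    for k, name in enumerate(DEFAULT_SIGNATURES):
        start = k * step
        idx = np.arange(start, start + c.n_signature_genes)
        sets[name] = list(genes[idx])
        sig_members.update(idx.tolist())
        X[idx] += c.loading * z[None, :]

    # coexpression modules on genes disjoint from the signatures
    first_free = max(sig_members) + 1 if sig_members else 0
    module_labels = pd.Series("background", index=genes, name="module")
    factors = rng.normal(0.0, c.module_factor_sd, size=(c.n_modules, c.n_samples))
    for m in range(c.n_modules):
        idx = np.arange(first_free + m * c.module_size,
                        first_free + (m + 1) * c.module_size)
        name = f"module_{m + 1}"
        sets[name] = list(genes[idx])
        module_labels.iloc[idx] = name
        X[idx] += factors[m][None, :]
    module_labels.iloc[sorted(sig_members)] = "signature"

    expr = pd.DataFrame(X, index=genes, columns=samples)

    # clinical outcomes from the latent factor
    lin = c.alpha + c.gamma * z + c.gamma_mod * factors[0] if c.n_modules else c.alpha + c.gamma * z
    pcr = rng.random(c.n_samples) < 1.0 / (1.0 + np.exp(-lin))
    response = np.where(pcr, "pCR", "RD")

    def draw_times(rate_scale: float) -> tuple[np.ndarray, np.ndarray]:
        rate = c.h0 * rate_scale * np.exp(-c.delta * z)
        if c.weibull_shape is None:
            t = rng.exponential(1.0 / rate)
        else:
            k = c.weibull_shape
            t = rng.weibull(k, size=c.n_samples) / rate ** (1.0 / k)
        cens = rng.uniform(0.0, c.censor_max, size=c.n_samples)
        return np.minimum(t, cens), (t <= cens).astype(int)

    os_time, os_event = draw_times(1.0)
    pfi_time, pfi_event = draw_times(c.pfi_rate_ratio)

    clinical = pd.DataFrame(
        {
            "response": response,
            "os_time": os_time,
            "os_event": os_event,
            "pfi_time": pfi_time,
            "pfi_event": pfi_event,
            "age": np.round(rng.normal(56.0, 11.0, size=c.n_samples), 1),
            "stage": rng.choice(["I", "II", "III"], size=c.n_samples, p=[0.25, 0.5, 0.25]),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SyntheticCohort(
        expr=expr,
        sets=sets,
        clinical=clinical,
        latent=pd.Series(z, index=samples, name="z"),
        module_labels=module_labels,
        module_factors=pd.DataFrame(
            factors.T, index=samples,
            columns=[f"module_{m + 1}" for m in range(c.n_modules)],
        ),
        config=c,
    )


def generate_hub_expression(
    n_genes: int = 1500,
    n_samples: int = 150,
    n_hubs: int = 5,
    seed: int = 0,
    load_min: float = 0.27,
    load_max: float = 0.9,
    load_exponent: float = 2.0,
    background_fraction: float = 0.4,
) -> pd.DataFrame:
    """Expression whose coexpression network has scale-free topology.

    Hub genes load on one of ``n_hubs`` independent latent factors with
    loadings drawn from a truncated Pareto law (density proportional to
    loading^-(load_exponent + 1) on [load_min, load_max]): soft-threshold
    connectivity scales as loading^beta, so a Pareto loading tail yields a
    power-law connectivity tail, the classic scale-free signature. A
    ``background_fraction`` of independent-noise genes supplies the
    connectivity floor under which weakly loaded genes disappear, as in real
    expression data. Unit marginal variance by construction. Returns a
    genes x samples DataFrame.
    """
    rng = np.random.default_rng(seed)
    genes = [f"H{i:05d}" for i in range(n_genes)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    n_hub_genes = int(n_genes * (1.0 - background_fraction))
    hub = np.arange(n_hub_genes) % n_hubs
    factors = rng.standard_normal((n_hubs, n_samples))
    # inverse-CDF draw from the truncated Pareto on [load_min, load_max]
    f_max = 1.0 - (load_min / load_max) ** load_exponent
    u = rng.random(n_hub_genes) * f_max
    load = load_min * (1.0 - u) ** (-1.0 / load_exponent)
    noise = rng.standard_normal((n_hub_genes, n_samples))
    hub_x = load[:, None] * factors[hub] + np.sqrt(1.0 - load**2)[:, None] * noise
    bg_x = rng.standard_normal((n_genes - n_hub_genes, n_samples))
    return pd.DataFrame(np.vstack([hub_x, bg_x]), index=genes, columns=samples)


def closed_form_latent_auc(gamma: float, alpha: float = -0.85) -> float:
    """AUC of the latent factor z for outcomes y ~ Bernoulli(logistic(alpha + gamma z)).

    Computed by numerical integration over the class-conditional densities
    of z; 0.5 at gamma = 0 and increasing toward 1 with gamma.
    """
    if gamma == 0:
        return 0.5
    grid = np.linspace(-9.0, 9.0, 20001)
    phi = stats.norm.pdf(grid)
    p = 1.0 / (1.0 + np.exp(-(alpha + gamma * grid)))
    f1 = phi * p          # unnormalized density of z | y=1
    f0 = phi * (1.0 - p)  # z | y=0
    p1 = np.trapezoid(f1, grid)
    p0 = np.trapezoid(f0, grid)
    cdf0 = integrate.cumulative_trapezoid(f0, grid, initial=0.0) / p0
    return float(np.trapezoid(f1 / p1 * cdf0, grid))


def gamma_for_latent_auc(target_auc: float, alpha: float = -0.85) -> float:
    """Logistic slope gamma whose latent AUC equals ``target_auc``."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target AUC must lie in (0.5, 1)")
    return float(optimize.brentq(
        lambda g: closed_form_latent_auc(g, alpha) - target_auc, 1e-6, 30.0
    ))
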