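import pandas as pd
import pytest

from iescore import GeneratorConfig, generate
from iescore.ies import DEFAULT_SIGNATURES
from iescore.ssgsea import score_all


@pytest.fixture
def small_expr():
    """4 genes x 3 samples, distinct values."""
    return pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0], "s3": [2.0, 1.0, 4.0, 3.0]},
        index=["A", "B", "C", "D"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default design (seeded)."""
    return generate(GeneratorConfig(seed=1, n_samples=123, n_genes=1000))


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    sig = {k: default_cohort.sets[k] for k in DEFAULT_SIGNATURES}
    return score_all(default_cohort.expr, sig, tau=0.25, normalize=True)


def random_expression(rng, n_genes, n_samples):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return pd.DataFrame(rng.standard_normal((n_genes, n_samples)), index=genes, columns=samples)
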