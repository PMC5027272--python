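import pytest

from embryomix.mixture import MixtureQuery, estimate_rate
from embryomix.synthetic import ExpressionConfig, simulate_expression

# printed cohort counts of the study the package models
Q1 = estimate_rate(24, 232)
Q2 = estimate_rate(107, 237)


@pytest.fixture(scope="session")
def cohort_rates():
    return Q1, Q2


@pytest.fixture
def base_query():
    """The 232-embryo cohort with 24 term offspring and k=20 evidence."""
    return MixtureQuery(N=232, T=24, q1=Q1, q2=Q2, k_list=(20,), n=9)


@pytest.fixture(scope="session")
def small_study():
    """A small sibling-paired study: 500 genes, 20 of them truly DE."""
    cfg = ExpressionConfig(n_genes=500, n_de_genes=20, replicate_fraction=0.1)
    return simulate_expression(cfg, seed=42)
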