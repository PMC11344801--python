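import pytest

from fluxcap import FixtureSpec, apply_media, make_toy_gem
from fluxcap.synthetic import chain_media


@pytest.fixture
def two_chain():
    """Two parallel 3-step chains, one planted essential gene, all rule
    categories represented.  Analytic optimum 10 (uptake 5 per chain)."""
    spec = FixtureSpec(seed=1, n_linear_chains=2, chain_length=3,
                       planted_essentials=("GE1",))
    model, truth = make_toy_gem(spec)
    return model, truth


@pytest.fixture
def two_chain_media(two_chain):
    """The two-chain model with its chain medium applied."""
    model, truth = two_chain
    media = chain_media(model, truth)
    return apply_media(model, media), truth, media


@pytest.fixture
def single_chain():
    """One 3-step chain: every chain reaction is growth-essential."""
    spec = FixtureSpec(seed=3, n_linear_chains=1, chain_length=3,
                       include_rule_categories=("one-gene",))
    return make_toy_gem(spec)
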