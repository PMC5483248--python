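import numpy as np
import pytest

from crescan import (
    BackgroundModel,
    FrequencyMatrix,
    Pssm,
    build_count_matrix,
    build_pssm,
    cre_like_frequency_matrix,
    sample_sites,
    to_frequencies,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def cre_freqs() -> FrequencyMatrix:
    """The default 14-position cre-type operator frequency matrix."""
    return cre_like_frequency_matrix()


@pytest.fixture
def trained_pssm(cre_freqs) -> Pssm:
    """PSSM trained on 44 sites sampled from the cre-like motif."""
    sites = sample_sites(cre_freqs, 44, seed=7)
    freqs = to_frequencies(build_count_matrix(sites), pseudocount=0.5)
    return build_pssm(freqs, BackgroundModel.uniform())


def random_pssm(rng, k: int = 6, scale: float = 2.0) -> Pssm:
    """A PSSM with i.i.d. normal scores — no probabilistic meaning, just
    an arbitrary additive matrix for oracle-equivalence checks."""
    return Pssm(w=rng.normal(0.0, scale, size=(4, k)))


def random_frequency_matrix(rng, k: int) -> FrequencyMatrix:
    f = rng.dirichlet(np.ones(4), size=k).T
    return FrequencyMatrix(f=f)
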