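import numpy as np
import pytest

from fcmodules import ExpressionMatrix, gen_mixture, run_ica, svd_whiten


@pytest.fixture(scope="session")
def laplace_mixture():
    """Noiseless orthogonal mixture of 3 Laplace sources (g=2000)."""
    return gen_mixture(2000, 3, source_family="laplace",
                       mixing="orthogonal", noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def recovered(laplace_mixture):
    """Whitened data and an ICA solution for the standard mixture."""
    w = svd_whiten(laplace_mixture.as_expression_matrix())
    sol = run_ica(w, backend="logcosh", seed=0, max_iter=500)
    return w, sol


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix():
    vals = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]])
    return ExpressionMatrix(vals, ["g1", "g2", "g3"], ["s1", "s2"])
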