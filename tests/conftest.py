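import numpy as np
import pytest

from morphgen.phantoms import PhantomSpec, render_phantom, sample_covariates


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, bias-free phantom spec (geometry exactly observable)."""
    return PhantomSpec(noise_sd=0.0, bias_field_strength=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_spec():
    return PhantomSpec(noise_sd=0.02, bias_field_strength=0.05, seed=11)


@pytest.fixture(scope="session")
def small_corpus(noisy_spec):
    """Ten noisy phantoms with covariates (session-cached)."""
    records = sample_covariates(10, noisy_spec)
    return [render_phantom(r, noisy_spec) for r in records]
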