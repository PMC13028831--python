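import numpy as np
import pytest

from gonadnmr.synth import CohortConfig


def sex_effect_matrix(n_male, n_female, n_vars, effect_idx=(), log2fc=1.0,
                      cv=0.3, noise_sd=0.05, seed=0):
    """Concentration-like feature matrix with optional sex-shifted variables.

    Mirrors the cohort concentration model: per-sample values are
    ``2^(±log2fc/2)`` times a log-normal factor of coefficient of
    variation ``cv`` plus additive noise.  Returns (X, y) with y coded
    -1 (male) / +1 (female).
    """
    rng = np.random.default_rng(seed)
    n = n_male + n_female
    y = np.array([-1] * n_male + [1] * n_female)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    X = np.exp(rng.normal(0.0, sigma, size=(n, n_vars)))
    for j in effect_idx:
        X[:, j] *= 2.0 ** (y * log2fc / 2.0)
    X += rng.normal(0.0, noise_sd, size=X.shape)
    return X, y


@pytest.fixture
def effect_matrix_factory():
    return sex_effect_matrix


@pytest.fixture
def small_cfg():
    """Reduced-grid cohort configuration for fast spectrum tests."""
    return CohortConfig(seed=11, noise_sd=0.0, grid_points=8192)
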