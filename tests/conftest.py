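import numpy as np
import pytest

import scdgd
from scdgd import simulate


@pytest.fixture(scope="session")
def fixture_bundle():
    """The standard ground-truth fixture: K=3, m=2, G=50, n=600, seed 0."""
    gt, data, labels, true_z, report = scdgd.default_fixture()
    return gt, data, labels, true_z, report


@pytest.fixture(scope="session")
def trained(fixture_bundle):
    """Unsupervised fit on the fixture with default settings, 300 epochs."""
    _, data, _, _, _ = fixture_bundle
    config = scdgd.TrainConfig(
        n_components=3, latent_dim=2, epochs=300, batch_size=128, seed=0
    )
    decoder, gmm, reps, history = scdgd.fit(data, config)
    return decoder, gmm, reps, history, config


@pytest.fixture(scope="session")
def trained_supervised(fixture_bundle):
    """Supervised fit on the fixture (labels = true components)."""
    _, data, labels, _, _ = fixture_bundle
    config = scdgd.TrainConfig(
        n_components=3,
        latent_dim=2,
        epochs=300,
        batch_size=128,
        seed=0,
        supervised=True,
    )
    decoder, gmm, reps, history = scdgd.fit(data, config, labels=labels)
    return decoder, gmm, reps, history, config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_gmm(rng, n_components=3, dim=2):
    """A random, asymmetric mixture instance for oracle comparisons."""
    gmm = scdgd.GaussianMixture(n_components, dim, rng=rng)
    gmm.means = rng.standard_normal((n_components, dim)) * 2.0
    gmm.neg_log_var = rng.uniform(-1.0, 2.0, size=(n_components, dim))
    gmm.coeffs = rng.standard_normal(n_components)
    return gmm
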