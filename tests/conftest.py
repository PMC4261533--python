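import numpy as np
import pytest

from rankcost import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def separable_data():
    """Linearly separable imbalanced fixture: 20 vs 80, class means 6 sd apart."""
    return generate_synthetic(SyntheticSpec(n_pos=20, n_neg=80, dim=2, separation=6, seed=7))


@pytest.fixture(scope="session")
def moderate_data():
    """Overlapping-classes fixture with nominal attributes and missing cells."""
    return generate_synthetic(
        SyntheticSpec(n_pos=30, n_neg=170, dim=5, separation=2,
                      n_nominal=2, missing_rate=0.05, seed=4)
    )


@pytest.fixture(scope="session")
def null_data():
    """No-signal fixture: identical class distributions (separation 0)."""
    return generate_synthetic(SyntheticSpec(n_pos=20, n_neg=80, dim=2, separation=0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ranking_instance(rng, max_n=50):
    """Random labels (both classes present), scores, and margin for oracles."""
    from rankcost import build_pairs

    n = int(rng.integers(2, max_n + 1))
    labels = np.where(rng.random(n) < 0.3, 1, -1)
    labels[0], labels[1 % n] = 1, -1  # both classes present
    scores = rng.normal(size=n) * rng.uniform(0.1, 3.0)
    tau = float(rng.uniform(0.1, 2.0))
    return labels, scores, tau, build_pairs(labels)
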