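import numpy as np
import pytest

import pclfsx as px


@pytest.fixture
def balanced_dataset() -> px.Dataset:
    """1000 samples, 30 features, 10 informative, well-separated classes."""
    spec = px.SynthSpec(
        n_samples=1000,
        n_features=30,
        n_informative=10,
        class_weights=(0.5, 0.5),
        class_sep=2.0,
        seed=7,
    )
    return px.generate_dataset(spec)


@pytest.fixture
def imbalanced_dataset() -> px.Dataset:
    spec = px.SynthSpec(
        n_samples=1000,
        n_features=30,
        n_informative=10,
        class_weights=(0.9, 0.1),
        class_sep=2.0,
        seed=11,
    )
    return px.generate_dataset(spec)


def make_grid(values) -> px.GridScores:
    """Wrap a plain F1 vector (1-based notation g_1..g_n) as GridScores."""
    g = np.asarray(values, dtype=float)
    ranking = px.RankedFeatures(order=np.arange(g.size), scores=np.zeros(g.size))
    return px.GridScores(g=g, order_ref=ranking)
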