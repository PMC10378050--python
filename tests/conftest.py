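import numpy as np
import pytest

from drmargin import (
    MarginConfig,
    SyntheticImageConfig,
    generate_dataset,
    make_pairing,
    normalize_rows,
)


def random_double_view_batch(rng, n_sources=None, dim=None, n_labels=3):
    """A random unit-norm double-viewed batch with repeated labels."""
    n = n_sources or int(rng.integers(2, 9))
    d = dim or int(rng.integers(2, 17))
    batch = normalize_rows(rng.normal(size=(2 * n, d)))
    labels = rng.integers(0, n_labels, size=n)
    return batch, np.concatenate([labels, labels]), make_pairing(n)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """30 synthetic fundus-like images, 6 per grade, 32x32."""
    out = tmp_path_factory.mktemp("tinydata")
    cfg = SyntheticImageConfig(size=32, seed=7)
    return generate_dataset(cfg, (6, 6, 6, 6, 6), out)


@pytest.fixture
def margin_cfg():
    return MarginConfig(m_u=0.2, m_v=0.1, tau=0.05, lam=1.0)
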