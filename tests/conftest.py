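import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rpos.core import LabeledExpressionData, SelectionConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return SelectionConfig()


def make_data(values, labels, gene_ids=None):
    """Build a LabeledExpressionData, silencing the small-class warning
    that tiny fixtures trigger."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(p)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LabeledExpressionData(
            values, gene_ids, [f"s{i}" for i in range(n)], np.asarray(labels)
        )


def random_labels(rng, n, min_per_class=2):
    """Random binary labels with both classes represented."""
    while True:
        lab = rng.integers(0, 2, n)
        if min((lab == 0).sum(), (lab == 1).sum()) >= min_per_class:
            return lab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
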