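from __future__ import annotations

import numpy as np
import pytest

from stressid.data_model import Dataset
from stressid.synthetic import GeneratorConfig, generate_cohort, table3_fixture


@pytest.fixture(scope="session")
def table3() -> Dataset:
    return table3_fixture()


def make_cohort(seed, n=300, elevated=7.5, baseline=2.5, spread=0.8,
                proportions=(1 / 3, 1 / 3, 1 / 3)):
    """Well-separated planted cohort used by the clustering tests."""
    config = GeneratorConfig(
        n=n,
        proportions=proportions,
        elevated_mean=elevated,
        baseline_mean=baseline,
        spread=spread,
        seed=seed,
    )
    return generate_cohort(config)


def ari(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(list(labels_a), list(labels_b))


def planted_labels_as_ints(labels):
    order = {}
    out = []
    for lab in labels:
        out.append(order.setdefault(lab, len(order)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
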