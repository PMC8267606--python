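from __future__ import annotations

import numpy as np
import pytest

from catcad.bank import Bank, ItemParams, ItemSpec
from catcad.synthetic import gen_bank, gen_diagnosis, gen_responses


@pytest.fixture
def two_item_bank() -> Bank:
    """Two binary items in one subdomain, asymmetric slopes."""
    items = [ItemSpec("i1", "s1", 2), ItemSpec("i2", "s1", 2)]
    params = {
        "i1": ItemParams(1.8, 0.0, (0.0,)),
        "i2": ItemParams(0.9, 0.0, (0.0,)),
    }
    return Bank(items=items, params=params, subdomains=("s1",))


@pytest.fixture
def mixed_bank() -> Bank:
    """Five calibrated items over two subdomains, 2-4 categories."""
    items = [
        ItemSpec("a1", "s1", 2),
        ItemSpec("a2", "s1", 3),
        ItemSpec("a3", "s1", 4),
        ItemSpec("b1", "s2", 3),
        ItemSpec("b2", "s2", 4),
    ]
    params = {
        "a1": ItemParams(1.5, 0.6, (-0.3,)),
        "a2": ItemParams(1.1, 0.4, (-1.0, 0.8)),
        "a3": ItemParams(2.0, 0.9, (-1.5, 0.0, 1.4)),
        "b1": ItemParams(0.8, 0.7, (-0.5, 1.1)),
        "b2": ItemParams(1.3, 0.5, (-2.0, -0.4, 1.0)),
    }
    return Bank(items=items, params=params, subdomains=("s1", "s2"))


@pytest.fixture(scope="session")
def fixture_truth():
    """A 30-item calibrated synthetic bank used across CAT tests."""
    return gen_bank(
        n_items=30,
        subdomain_sizes={"s1": 8, "s2": 7, "s3": 8, "s4": 7},
        seed=301,
    )


@pytest.fixture(scope="session")
def fixture_responses(fixture_truth):
    return gen_responses(fixture_truth, n_persons=120, seed=302)


@pytest.fixture(scope="session")
def cad_data():
    """Responses + labels with a strong latent liability signal."""
    truth = gen_bank(
        n_items=30,
        subdomain_sizes={"s1": 8, "s2": 7, "s3": 8, "s4": 7},
        seed=401,
    )
    responses = gen_responses(truth, n_persons=400, seed=402)
    labels = gen_diagnosis(truth, prevalence_target=0.284, signal_strength=2.5, seed=403)
    return truth, responses, labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
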