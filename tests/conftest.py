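import pytest

from minetkit.gsmm_io import make_demo_models, make_toy_model
from minetkit.seedset import seed_set_for_model


@pytest.fixture
def chain_model_a():
    """a -> b -> c: seed {a}."""
    return make_toy_model(["a -> b", "b -> c"], model_id="A")


@pytest.fixture
def chain_model_b():
    """c -> d -> a: seed {c}; complements chain_model_a."""
    return make_toy_model(["c -> d", "d -> a"], model_id="B")


@pytest.fixture
def seed_set_a(chain_model_a):
    return seed_set_for_model(chain_model_a)


@pytest.fixture
def seed_set_b(chain_model_b):
    return seed_set_for_model(chain_model_b)


@pytest.fixture
def linear_fba_model():
    """Uptake bound of 10 is the only constraint: FBA optimum = 10."""
    return make_toy_model(
        [
            ("EX_g", "g ->", -10.0, 1000.0),
            ("P1", "g -> x"),
            ("Growth", "x ->", 0.0, 1000.0),
        ],
        model_id="linear",
        objective="Growth",
    )


@pytest.fixture
def branched_fba_model():
    """Two routes g->x: direct (P1) and via y (P2a+P2b); pFBA must take P1."""
    return make_toy_model(
        [
            ("EX_g", "g ->", -10.0, 1000.0),
            ("P1", "g -> x"),
            ("P2a", "g -> y"),
            ("P2b", "y -> x"),
            ("Growth", "x ->", 0.0, 1000.0),
        ],
        model_id="branched",
        objective="Growth",
    )


@pytest.fixture(scope="session")
def demo_models():
    return make_demo_models()
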