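import numpy as np
import pytest

from minnet.evaluate import GrowthEvaluator
from minnet.evolve import MinimiserConfig, minimise
from minnet.synthetic import ToySpec, make_fixture, make_random_toy


@pytest.fixture(scope="session")
def toy1():
    return make_fixture("TOY1")


@pytest.fixture(scope="session")
def toy2():
    return make_fixture("TOY2")


@pytest.fixture(scope="session")
def toy1_json(tmp_path_factory):
    """TOY1 written to disk and re-read, exercising the I/O boundary."""
    from minnet.model import write_json

    path = tmp_path_factory.mktemp("models") / "TOY1.json"
    write_json(make_fixture("TOY1"), path)
    return path


@pytest.fixture(scope="session")
def toy1_collection(toy1):
    """A small but exhaustively-correct minimise run on TOY1."""
    cfg = MinimiserConfig(population_size=10, max_generations=30,
                          growth_threshold_fraction=0.99, seed=11)
    return minimise(toy1, cfg)


def small_random_toys(n_models: int, max_deletable: int = 10):
    """Deterministic stream of random layered toys for oracle testing."""
    toys = []
    seed = 0
    while len(toys) < n_models:
        seed += 1
        spec = ToySpec(
            n_layers=1 + seed % 3,
            redundancy=1 + (seed // 3) % 3,
            complex_size=1 + seed % 2,
            n_exchanges=1,
            seed=seed,
        )
        model = make_random_toy(spec)
        if model.n_genes - model.n_essential <= max_deletable:
            toys.append(model)
    return toys


@pytest.fixture(scope="session")
def redundant_toy():
    """Layered toy with one mandatory step and two redundant layers.

    Layer path counts under seed 2060 are (1, 3, 3): the transporter and
    the single layer-0 gene are retained in every MMN, while the six
    isoenzyme genes of layers 1-2 are individually dispensable.
    """
    model = make_random_toy(ToySpec(n_layers=3, redundancy=3,
                                    complex_size=1, n_exchanges=1,
                                    seed=2060))
    return model


@pytest.fixture(scope="session")
def shared_evaluator(toy1):
    return GrowthEvaluator(toy1)
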