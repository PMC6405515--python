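import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from liverflux.netmodel import Metabolite, NetworkModel, Reaction
from liverflux.synthetic import ToyNetworkSpec, make_toy_liver_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Default toy liver network with both bound sets and planted truths."""
    return make_toy_liver_network(ToyNetworkSpec())


@pytest.fixture()
def chain_model():
    """Uptake (<=10) -> conversion -> secretion; bottleneck capability 10."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -10.0, 0.0),
        Reaction("CONV", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0),
    ]
    return NetworkModel(mets, rxns, id="chain")


def random_small_model(rng: np.random.Generator, n_rxns: int = 6) -> NetworkModel:
    """Random feasible network (zero flux always feasible) for oracle checks."""
    n_mets = rng.integers(2, 4)
    mets = [Metabolite(f"M{i}") for i in range(n_mets)]
    rxns = []
    has_uptake_exchange = set()
    for j in range(n_rxns):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {
            f"M{i}": float(rng.choice([-2, -1, 1, 2])) for i in chosen
        }
        if len(stoich) == 1:
            # one secretion-capable exchange per metabolite keeps the
            # engine's exchange choice unambiguous for oracle comparisons
            met, coef = next(iter(stoich.items()))
            if coef < 0:
                if met in has_uptake_exchange:
                    stoich[met] = abs(coef)
                else:
                    has_uptake_exchange.add(met)
        lo = float(rng.choice([-5.0, -2.0, 0.0]))
        hi = float(rng.choice([0.0, 2.0, 5.0]))
        if lo > hi:
            lo, hi = hi, lo
        rxns.append(Reaction(f"R{j}", stoich, lo, hi))
    return NetworkModel(mets, rxns, id="random")
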