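import numpy as np
import pytest

from boolcore import BooleanNetwork, TransferFunction


@pytest.fixture
def two_node_cycle():
    """A copies B's previous state and vice versa: period-2 dynamics."""
    return BooleanNetwork(
        ["A", "B"],
        {"A": TransferFunction.from_table("A", ("B",), [0, 1]),
         "B": TransferFunction.from_table("B", ("A",), [0, 1])})


@pytest.fixture
def constant_net():
    """Three nodes pinned at 0 regardless of input."""
    nodes = ["A", "B", "C"]
    funcs = {g: TransferFunction.from_table(g, (nodes[0],), [0, 0])
             for g in nodes}
    return BooleanNetwork(nodes, funcs)


def random_explicit_network(n_nodes, k, bias, seed):
    """Random network: each node gets k random distinct inputs and a
    Bernoulli(bias) truth table (test helper, independent of null models)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    funcs = {}
    for g in nodes:
        inputs = tuple(nodes[i]
                       for i in rng.choice(n_nodes, size=k, replace=False))
        table = (rng.random(2 ** k) < bias).astype(np.uint8)
        funcs[g] = TransferFunction.from_table(g, inputs, table)
    return BooleanNetwork(nodes, funcs)


@pytest.fixture
def random_net_factory():
    return random_explicit_network
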