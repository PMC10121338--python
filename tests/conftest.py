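import itertools

import numpy as np
import pandas as pd
import pytest

from wigamine.io import ExpressionDataset
from wigamine.wiga import NetworkSet, WigaNetwork


def random_networkset(rng, n_nodes=6, n_networks=6, p=0.3) -> NetworkSet:
    """Random small two-population network instance for oracle tests."""
    nodes = tuple(f"n{i}" for i in range(n_nodes))
    pairs = [(a, b) for a, b in itertools.combinations(nodes, 2)]
    nets = []
    for i in range(n_networks):
        weights = {
            e: round(float(rng.uniform(0.05, 1.0)), 3) for e in pairs if rng.random() < p
        }
        nets.append(WigaNetwork(sample_id=f"s{i:02d}", label="", nodes=nodes, weights=weights))
    split = int(rng.integers(1, n_networks)) if n_networks > 1 else 1
    return NetworkSet(n1=tuple(nets[:split]), n2=tuple(nets[split:]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_networkset() -> NetworkSet:
    """Hand-built fixture: 4 nodes, 5 networks (3 cases + 2 controls).

    The triangle a-b-c recurs in the cases; controls carry mostly b-c/c-d.
    """
    nodes = ("a", "b", "c", "d")

    def net(sid, label, weights):
        return WigaNetwork(sample_id=sid, label=label, nodes=nodes, weights=weights)

    n1 = (
        net("case1", "case", {("a", "b"): 0.9, ("a", "c"): 0.8, ("b", "c"): 0.7}),
        net("case2", "case", {("a", "b"): 0.8, ("a", "c"): 0.9, ("b", "c"): 0.6, ("c", "d"): 0.5}),
        net("case3", "case", {("a", "b"): 0.4, ("b", "c"): 0.9}),
    )
    n2 = (
        net("ctrl1", "control", {("b", "c"): 0.8, ("c", "d"): 0.9}),
        net("ctrl2", "control", {("c", "d"): 0.7}),
    )
    return NetworkSet(n1=n1, n2=n2)


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x 4 samples with hand-checkable moments."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 10.0],
            "s2": [3.0, 4.0, 12.0],
            "s3": [5.0, 6.0, 8.0],
            "s4": [7.0, 8.0, 14.0],
        },
        index=["gA", "gB", "gC"],
    )
    labels = pd.Series(["case", "case", "control", "control"], index=["s1", "s2", "s3", "s4"])
    return ExpressionDataset(values=values, labels=labels)
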