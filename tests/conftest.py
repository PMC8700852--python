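import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epitriclust as et

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor():
    """3 groups x 4 genes x 5 bins; first two groups share profiles on the
    first three genes, third group is anti-correlated there."""
    base = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 1.0, 4.0, 3.0, 6.0],
            [0.5, 1.5, 0.5, 2.5, 3.5],
            [1.0, 1.0, 1.0, 1.0, 2.0],
        ]
    )
    values = np.stack(
        [
            base,
            base * 2.0 + 1.0,  # affine copy: r == 1 with base
            base[:, ::-1],  # reversed: strongly negative vs base
        ]
    )
    return et.MarkTensor(
        mark="H3K4me3",
        groups=["A", "B", "C"],
        genes=["g1", "g2", "g3", "g4"],
        n_bins=5,
        values=values,
    )


@pytest.fixture
def zero_noise_world():
    """Default 3-block planted model at noise_sd=0, with mined artifacts."""
    model = et.default_model(seed=7)
    model.noise_sd = 0.0
    tensors, truth = et.generate(model)
    min_support = et.minimum_support_from_fraction(len(model.genes), 0.10)
    transactions = {m: et.build_transactions(t, 0.65) for m, t in tensors.items()}
    biclusters = {
        m: et.mine_mark_biclusters(tx, min_support)
        for m, tx in transactions.items()
    }
    triclusters = et.mine_triclusters(biclusters, min_support)
    return {
        "model": model,
        "tensors": tensors,
        "truth": truth,
        "min_support": min_support,
        "transactions": transactions,
        "biclusters": biclusters,
        "triclusters": triclusters,
    }


def random_transactions(rng, n_items=None, n_tx=None):
    """Random itemset transactions over a small alphabet (for oracles)."""
    n_items = n_items or int(rng.integers(1, 11))
    n_tx = n_tx or int(rng.integers(1, 51))
    alphabet = [f"i{k}" for k in range(n_items)]
    tx = []
    for _ in range(n_tx):
        density = rng.uniform(0.1, 0.8)
        tx.append(frozenset(a for a in alphabet if rng.random() < density))
    return tx
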