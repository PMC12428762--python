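import numpy as np
import pandas as pd
import pytest

from eggshell import (
    Dataset,
    apply_combat,
    default_config,
    fit_combat,
    generate_dataset_with_truth,
)


def make_table(rows):
    """Build an egg table DataFrame from (batch, L, a, b, obs) tuples."""
    recs = []
    for i, (batch, L, a, b, obs) in enumerate(rows):
        recs.append(
            {
                "batch": batch,
                "egg_id": f"e{i}",
                "L": L,
                "a": a,
                "b": b,
                "obs1": obs[0],
                "obs2": obs[1],
                "obs3": obs[2],
                "obs4": obs[3],
            }
        )
    return pd.DataFrame(recs)


def random_dataset(rng, n=60, n_batches=2):
    """Unstructured dataset: MVN colors, random observer labels."""
    colors = rng.multivariate_normal(
        [80.0, -6.0, 10.0],
        [[16.0, 0.5, -2.0], [0.5, 2.0, 1.0], [-2.0, 1.0, 9.0]],
        size=n,
    )
    obs = rng.integers(1, 5, size=(n, 4))
    batches = [f"B{i % n_batches + 1}" for i in range(n)]
    rows = [
        (batches[i], colors[i, 0], colors[i, 1], colors[i, 2], obs[i])
        for i in range(n)
    ]
    return Dataset(make_table(rows))


@pytest.fixture(scope="session")
def calibrated():
    """Full-size synthetic dataset under the calibrated defaults."""
    cfg = default_config(seed=123)
    ds, truth = generate_dataset_with_truth(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def corrected_full(calibrated):
    """Batch-corrected version of the calibrated dataset."""
    _, ds, _ = calibrated
    model = fit_combat(ds)
    return apply_combat(model, ds)


@pytest.fixture
def rng():
    return np.random.default_rng(20250829)
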