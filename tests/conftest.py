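import numpy as np
import pytest

from modmet import ExpressionDataset, ExpressionSimSpec, simulate_expression


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """4 genes x 6 samples, two groups of three, handcrafted values."""
    values = np.array(
        [
            [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],   # clean separation, case high
            [1.0, 2.0, 3.0, 5.0, 6.0, 7.0],   # clean separation, case low
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],   # constant
            [3.0, 1.0, 4.0, 2.0, 4.0, 5.0],   # mixed with a tie
        ]
    )
    samples = [f"s{i}" for i in range(6)]
    labels = {s: ("case" if i < 3 else "ctrl") for i, s in enumerate(samples)}
    return ExpressionDataset(["gA", "gB", "gC", "gD"], samples, values, labels)


@pytest.fixture
def null_dataset():
    """All-null simulated 200-gene dataset with two 30-sample groups."""
    spec = ExpressionSimSpec(
        n_genes=200,
        group_sizes={"normal": 30, "early": 30},
        modules={f"M{k}": list(range(k * 20, (k + 1) * 20)) for k in range(10)},
        seed=42,
    )
    dataset, _ = simulate_expression(spec)
    modules = {
        f"M{k}": [f"G{i:05d}" for i in range(k * 20, (k + 1) * 20)]
        for k in range(10)
    }
    return dataset, modules
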