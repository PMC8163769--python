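import numpy as np
import pandas as pd
import pytest

from driftscape import ExpressionMatrix, LandscapeFixture, generate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_expr():
    """5 genes x 4 cells with known variances and a constant gene."""
    values = np.array([
        [1.0, 0.0, 5.0, 2.0, 1.0],
        [2.0, 0.0, 1.0, 2.1, 1.0],
        [3.0, 0.0, 9.0, 1.9, 1.0],
        [4.0, 0.0, 5.0, 2.0, 1.0],
    ])
    meta = pd.DataFrame({"time": [0.0, 0.0, 1.0, 1.0]},
                        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"))
    return ExpressionMatrix(values=values, gene_names=list("ABCDE"),
                            cell_ids=[f"c{i}" for i in range(4)], meta=meta)


@pytest.fixture(scope="session")
def bistable_fixture():
    fx = LandscapeFixture(seed=0)
    expr, truth = generate(fx)
    return fx, expr, truth


@pytest.fixture(scope="session")
def bistable_snapshots(bistable_fixture):
    """Ground-truth latent snapshots plus planted growth rates per snapshot."""
    fx, expr, truth = bistable_fixture
    meta = expr.meta
    times = sorted(meta["time"].unique())
    masks = [(meta["time"] == t).to_numpy() for t in times]
    states = [truth.latent[m] for m in masks]
    growth = [truth.birth_rate[m] for m in masks]
    return times, states, growth
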