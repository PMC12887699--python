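import numpy as np
import pandas as pd
import pytest

import stnichekit as sk

# Test-scale study conditions: same structure as the defaults, sized so a
# single simulation runs in well under a second.
TEST_SIM = dict(n_genes=120, n_cells_per_sample=300, n_samples_per_group=2, grid_side=16)


def make_config(seed: int, **overrides) -> sk.SimulationConfig:
    params = {**TEST_SIM, **overrides}
    return sk.SimulationConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def sim():
    """One paired simulation shared by read-only tests."""
    cfg = make_config(seed=7)
    cells, spatial, design, truth = sk.simulate_paired(cfg)
    return cfg, cells, spatial, design, truth


@pytest.fixture()
def toy_counts():
    """5 single-gene cells with the classic QC threshold pattern."""
    totals = np.array([[500], [1500], [2000], [1200], [3000]])
    meta = pd.DataFrame(
        {
            "sample_id": ["s1"] * 5,
            "mito_fraction": [0.05, 0.20, 0.10, 0.14, 0.16],
        },
        index=pd.Index([f"c{i}" for i in range(5)]),
    )
    return sk.CountMatrix(
        counts=totals,
        obs_ids=meta.index,
        gene_ids=pd.Index(["g1"]),
        obs_meta=meta,
    )
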