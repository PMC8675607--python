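import numpy as np
import pandas as pd
import pytest

from coexkey import CountDataset, SimulationConfig, generate_dataset


def make_design(n_per_group: int = 5) -> pd.DataFrame:
    rows = []
    for cond in ("control", "salt"):
        for i in range(n_per_group):
            rows.append(
                {
                    "sample": f"{cond}_{i}",
                    "condition": cond,
                    "time_h": float(i),
                    "replicate": 1,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture
def small_dataset() -> CountDataset:
    rng = np.random.default_rng(11)
    design = make_design(5)
    counts = rng.poisson(50.0, size=(20, 10))
    genes = [f"g{i}" for i in range(20)]
    return CountDataset(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        design=design,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return generate_dataset(SimulationConfig(seed=7))


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down generator config for fast structural tests."""
    base = dict(
        n_genes=400,
        n_modules=2,
        module_sizes=(40, 35),
        n_key_genes_per_module=4,
        n_null_genes=325,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
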