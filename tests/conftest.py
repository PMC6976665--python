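import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from luniche import lui as luimod
from luniche import simdata
from luniche.tables import CountTable


@pytest.fixture(scope="session")
def sim_config():
    return simdata.SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_lui(sim_config):
    records = simdata.simulate_landuse(sim_config)
    means = luimod.region_means(records)
    return luimod.mean_lui(records, means, sim_config.year_from, sim_config.year_to)


@pytest.fixture(scope="session")
def sim_dataset(sim_config, sim_lui):
    """Factorial 13x2x2 simulated community plus its ground truth."""
    table, truth = simdata.simulate_community(sim_config, sim_lui)
    return table, truth


def make_table(counts, samples=None, taxa=None, metadata=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=taxa, columns=samples)
    return CountTable(df, metadata)


def make_metadata(samples, plots=None, species=None, plant_types=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "plot_id": plots or [f"p{i}" for i in range(n)],
            "species": species or ["Dactylis_glomerata"] * n,
            "plant_type": plant_types or ["phytometer"] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
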