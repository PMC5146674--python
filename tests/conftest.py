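import numpy as np
import pandas as pd
import pytest

from mecflux import OtuTable, SimConfig, simulate_batch_cycle


@pytest.fixture(scope="session")
def noiseless_sim():
    """One noise-free simulated cycle with the default 0 V-like routing."""
    return simulate_batch_cycle(SimConfig(seed=7).noiseless())


@pytest.fixture()
def small_otu_table():
    """A tiny hand-checkable OTU table with taxonomy over two domains."""
    counts = pd.DataFrame(
        {
            "s1": [40, 30, 20, 10, 0],
            "s2": [25, 25, 25, 25, 0],
            "s3": [1, 2, 3, 4, 90],
        },
        index=pd.Index(["t1", "t2", "t3", "t4", "t5"], name="#OTU ID"),
    )
    taxonomy = pd.Series(
        [
            "Bacteria;Proteobacteria;Deltaproteobacteria;o;f;Geobacter",
            "Bacteria;Firmicutes;Clostridia;o;f;Smithella",
            "Bacteria;Proteobacteria;Deltaproteobacteria;o;f;Syntrophobacter",
            "Archaea;Euryarchaeota;Methanobacteria;o;f;Methanobacterium",
            "Archaea;Euryarchaeota;Methanomicrobia;o;f;Methanosaeta",
        ],
        index=counts.index,
        name="taxonomy",
    )
    return OtuTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
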