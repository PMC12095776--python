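import numpy as np
import pandas as pd
import pytest

from gradr import Config
from gradr.core_io import CountTable
from gradr.simulate import SimulationSpec, simulate_cosedimentome


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic co-sedimentome shared by read-only tests."""
    return simulate_cosedimentome(SimulationSpec(rng_seed=11))


def make_count_table(rows, conditions=("A", "B"), replicates=2):
    """Build a CountTable from {entity: (counts_list, rpkm_list)} with
    samples ordered condition-major."""
    sample_ids = [f"{c}_r{i}" for c in conditions
                  for i in range(1, replicates + 1)]
    counts = pd.DataFrame({e: v[0] for e, v in rows.items()},
                          index=sample_ids).T
    rpkm = pd.DataFrame({e: v[1] for e, v in rows.items()},
                        index=sample_ids).T
    samples = pd.DataFrame(
        {"condition": [s.split("_")[0] for s in sample_ids],
         "replicate": [s.split("_")[1] for s in sample_ids]},
        index=pd.Index(sample_ids, name="sample_id"))
    return CountTable(counts=counts, rpkm=rpkm, samples=samples)


@pytest.fixture
def toy_counts():
    """Four RNAs exercising every branch of the expressed-RNA filter."""
    return make_count_table({
        # RPKM >= 0.5 in all replicates of condition A, plenty of reads
        "KEEP_A": ([50, 40, 2, 1], [0.6, 0.7, 0.1, 0.2]),
        # one replicate below 0.5 in every condition
        "DROP_RPKM": ([30, 30, 30, 30], [0.6, 0.4, 0.6, 0.4]),
        # high RPKM but too few reads everywhere
        "DROP_READS": ([9, 8, 7, 6], [5.0, 5.0, 5.0, 5.0]),
        # passes both rules in condition B
        "KEEP_B": ([1, 2, 25, 30], [0.1, 0.1, 1.5, 2.0]),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
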