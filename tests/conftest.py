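import numpy as np
import pandas as pd
import pytest

from metacgh.genome import Genome
from metacgh.io import AcghDataset, CloneMap
from metacgh.simulate import SyntheticSpec


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    """Two small chromosomes with centromeres at 4 Mb and 3 Mb."""
    return Genome({"1": 10_000_000, "2": 8_000_000},
                  {"1": 4_000_000, "2": 3_000_000})


@pytest.fixture(scope="session")
def toy_clone_map(toy_genome) -> CloneMap:
    """Clones every 1 Mb on both toy chromosomes (at 0.5, 1.5, ... Mb)."""
    rows = []
    for chrom, length in toy_genome.lengths.items():
        for pos in range(500_000, length, 1_000_000):
            rows.append((f"C{chrom}-{pos}", chrom, pos))
    df = pd.DataFrame(rows, columns=["clone_id", "chromosome", "position_bp"])
    return CloneMap.from_positions(df, toy_genome)


@pytest.fixture()
def toy_dataset(toy_clone_map) -> AcghDataset:
    rng = np.random.default_rng(42)
    n = 12
    log2 = rng.normal(0, 0.2, size=(n, len(toy_clone_map)))
    groups = np.array(["A"] * 6 + ["B"] * 6, dtype=object)
    return AcghDataset(toy_clone_map, log2, [f"s{i}" for i in range(n)], groups)


def small_spec(**kw) -> SyntheticSpec:
    """Reduced-genome synthetic spec used across tests."""
    defaults = dict(chromosomes=("17", "18", "20"), seed=0)
    defaults.update(kw)
    return SyntheticSpec(**defaults)
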