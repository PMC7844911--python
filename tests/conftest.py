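import numpy as np
import pytest

from peakmatcher import (
    GenomicInterval,
    MoleculeTable,
    Peak,
    simulate_assembly_pair,
)


@pytest.fixture(scope="session")
def clean_sim():
    """Unambiguous regime: 1-to-1 blocks, no duplicate collapse."""
    return simulate_assembly_pair(seed=11)


@pytest.fixture(scope="session")
def collapse_sim():
    """Duplicate-collapse regime: some source block pairs share one target block."""
    return simulate_assembly_pair(seed=13, collapse_fraction=0.3)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """Clean-regime fixture written out to files once per session."""
    out = tmp_path_factory.mktemp("simfiles")
    sim = simulate_assembly_pair(seed=11, out_dir=out)
    return sim, out


@pytest.fixture
def molecules():
    return MoleculeTable({"chr1": 100_000, "chr2": 50_000})


def random_peaks(rng: np.random.Generator, molecules: MoleculeTable,
                 n: int, width: int = 200, prefix: str = "p") -> list[Peak]:
    """Uniformly placed fixed-width peaks, names unique, overlap permitted."""
    names = list(molecules)
    peaks = []
    for i in range(n):
        mol = names[int(rng.integers(0, len(names)))]
        start = int(rng.integers(0, molecules[mol] - width))
        peaks.append(Peak(GenomicInterval(mol, start, start + width), f"{prefix}{i}"))
    return peaks
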