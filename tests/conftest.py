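import numpy as np
import pytest

from wisentmix.genomes import PseudoHaploidGenome, encode_sequence
from wisentmix.sim import SimConfig, simulate
from wisentmix.util import prefer_heap_allocations
from wisentmix.windows import partition_windows

prefer_heap_allocations()


def make_genome(name: str, chroms: dict[str, str], historical: bool = False):
    """Genome from literal sequence strings (test helper)."""
    return PseudoHaploidGenome(
        name=name,
        chroms={c: encode_sequence(s) for c, s in chroms.items()},
        historical=historical,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One moderately sized simulated dataset shared across tests.

    500 windows of 5 kb over five chromosomes, wisent-like ILS (tau = 1),
    damage on the introgressor sample and 20% missingness.
    """
    config = SimConfig(
        chrom_lengths={f"chr{i}": 500_000 for i in range(1, 6)},
        tau=1.0,
        mu=0.05,
        window_size=5_000,
        seed=42,
        delta=0.05,
        miss=0.2,
        historical=("P3",),
    )
    genomes, truth = simulate(config)
    windows = partition_windows(config.chrom_lengths, config.window_size)
    return config, genomes, truth, windows
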