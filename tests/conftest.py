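import numpy as np
import pytest

from deducemeth.io_formats import SampleSheet
from deducemeth.simulate import (
    constant_methylation_truth,
    simulate_genome,
    simulate_rrbs_reads,
    uniform_methylation_truth,
)


@pytest.fixture(scope="session")
def two_group_sheet() -> SampleSheet:
    return SampleSheet(
        sample_ids=tuple(f"s{i}" for i in range(1, 9)),
        group_labels=("g1",) * 4 + ("g2",) * 4,
    )


@pytest.fixture(scope="session")
def four_sample_sheet() -> SampleSheet:
    return SampleSheet(
        sample_ids=("s1", "s2", "s3", "s4"),
        group_labels=("g1", "g1", "g2", "g2"),
    )


@pytest.fixture(scope="session")
def sim_genome():
    return simulate_genome(60_000, gc_fraction=0.5, cpg_enrichment=8.0, seed=11)


@pytest.fixture(scope="session")
def fully_methylated_reads(sim_genome, four_sample_sheet):
    """Error-free fully methylated reads covering whole fragments from both strands."""
    truth = constant_methylation_truth(sim_genome, ["g1", "g2"], 1.0)
    reads, _ = simulate_rrbs_reads(
        sim_genome,
        truth,
        four_sample_sheet,
        depth=20,
        read_length=50,
        size_range=(30, 50),
        seed=12,
        paired_strands=True,
    )
    return reads


@pytest.fixture(scope="session")
def uniform_truth_dataset(sim_genome, two_group_sheet):
    """Simulation with per-(group, CpG) truth drawn Uniform(0, 1)."""
    truth = uniform_methylation_truth(sim_genome, ["g1", "g2"], seed=13)
    reads, truth_table = simulate_rrbs_reads(
        sim_genome,
        truth,
        two_group_sheet,
        depth=30,
        read_length=50,
        size_range=(30, 50),
        seed=14,
    )
    return truth, reads, truth_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)
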