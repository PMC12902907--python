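import numpy as np
import pytest

from ednamix import PopulationFrequencies, SampleCounts
from ednamix.markers import CONSERVED_6, HYPERVARIABLE_17, VARIABLE_14
from ednamix.simulate import ideal_config, realistic_config, run_scenario


@pytest.fixture
def pi_half() -> PopulationFrequencies:
    """Symmetric two-haplotype locus used in worked examples."""
    return PopulationFrequencies(("a", "b"), np.array([0.5, 0.5]))


@pytest.fixture
def variable14() -> PopulationFrequencies:
    return VARIABLE_14


@pytest.fixture
def conserved6() -> PopulationFrequencies:
    return CONSERVED_6


@pytest.fixture
def hyper17() -> PopulationFrequencies:
    return HYPERVARIABLE_17


def make_sample(counts, sample_id="s", ids=None, group=None) -> SampleCounts:
    counts = np.asarray(counts)
    if ids is None:
        ids = tuple(f"h{i + 1}" for i in range(counts.size))
    return SampleCounts(
        sample_id=sample_id,
        haplotype_ids=ids,
        read_counts=counts,
        replicate_group=group,
    )


@pytest.fixture
def ideal_dataset_small(variable14):
    """100 ideal-preset sites with the 14-haplotype marker (seeded)."""
    return run_scenario(ideal_config(variable14), 100, rng=1234)


@pytest.fixture
def realistic_dataset_small(variable14):
    """60 realistic-preset sites (seeded)."""
    return run_scenario(realistic_config(variable14), 60, rng=99)
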