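import numpy as np
import pytest

from hzkit import genio, syngen


@pytest.fixture
def small_dataset() -> genio.GenotypeDataset:
    """4 individuals x 3 loci with one missing call."""
    return genio.GenotypeDataset(
        individuals=["i1", "i2", "i3", "i4"],
        localities=["west", "west", "east", "east"],
        loci=["L1", "L2", "L3"],
        genotypes=np.array(
            [
                [0, 2, 1],
                [1, 2, -1],
                [2, 0, 0],
                [2, 0, 2],
            ]
        ),
    )


@pytest.fixture
def null_calls() -> genio.CallTable:
    return syngen.simulate_calls(syngen.CallScenario.null(seed=11))
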