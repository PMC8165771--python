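import numpy as np
import pandas as pd
import pytest

from cftriage.genome import GenomeDef
from cftriage.simulate import SimulationConfig


@pytest.fixture(scope="session")
def toy_genome() -> GenomeDef:
    return GenomeDef.toy()


@pytest.fixture(scope="session")
def small_genome() -> GenomeDef:
    """3 segments x 10 bins, uniform GC: GC correction reduces to a plain
    median normalization, so segment ratios are hand-computable."""
    n_seg, n_bins = 3, 10
    i = np.arange(n_seg * n_bins)
    return GenomeDef(
        pd.DataFrame(
            {
                "bin_id": [f"b{j}" for j in i],
                "segment_id": [f"s{j // n_bins}" for j in i],
                "chrom": [f"chr{1 + j // n_bins}" for j in i],
                "start": (i % n_bins) * 100,
                "end": (i % n_bins + 1) * 100,
                "gc": 0.5,
            }
        )
    )


@pytest.fixture()
def fast_cfg() -> SimulationConfig:
    """Scaled-down simulation for unit tests (fewer reads/fragments)."""
    return SimulationConfig(seed=7, n_healthy=6, n_patients=4, n_reads_swgs=1_000_000, n_fragments=4_000)
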