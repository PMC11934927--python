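import numpy as np
import pytest

from vrcrm.intervals import GenomicInterval, IntervalSet
from vrcrm.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture
def small_sim_config():
    """Reduced synthetic study for fast unit tests."""
    return SimConfig(
        seed=7,
        genome_length=300_000,
        n_chroms=2,
        n_genes=60,
        n_peaks_per_assay=40,
        planted_ch_count=9,
        planted_se_count=3,
        n_starr_elements=60,
        planted_cir_instances=6,
        planted_irhad_count=2,
        planted_hctfbs={"IR": 3, "kB": 3},
        planted_repeat_fraction=0.05,
    )


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=200):
    ivs = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, max_pos))
        ln = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(c, s, s + ln))
    return IntervalSet(ivs)
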