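import numpy as np
import pytest

from slafmap.simdata import SimConfig, simulate_dataset, simulate_meioses


@pytest.fixture(scope="session")
def small_truth():
    """Error-free truth genotypes: 3 chromosomes x 12 markers, 200 F2s."""
    cfg = SimConfig(
        n_chromosomes=3, chrom_lengths_cM=(80.0, 90.0, 100.0),
        markers_per_chrom=(12, 12, 12), n_individuals=200,
        polymorphic_fraction=1.0, seed=11,
    )
    return simulate_meioses(cfg)


@pytest.fixture(scope="session")
def shallow_dataset():
    """A shallow-coverage dataset: 2 chromosomes, 130 F2s at ~3x depth."""
    cfg = SimConfig(
        n_chromosomes=2, chrom_lengths_cM=(100.0, 100.0),
        markers_per_chrom=(20, 20), n_individuals=130,
        parent_depth_mean=40.0, offspring_depth_mean=3.0,
        seq_error_rate=0.01, missing_extra_rate=0.1,
        polymorphic_fraction=1.0,
        marker_positions=(np.linspace(0, 100, 20), np.linspace(0, 100, 20)),
        seed=5,
    )
    return simulate_dataset(cfg)
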