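import numpy as np
import pytest

from fourc import (
    BarcodeSpec,
    build_profile,
    generate_reference,
    process_library,
    simulate_reads,
)
from fourc.synthetic_data import SimulationConfig

# fixture barcodes: 6-mers with pairwise Hamming distance >= 3
BARCODES = [
    BarcodeSpec("S1", "ACGTGG"),
    BarcodeSpec("S2", "TGCACC"),
    BarcodeSpec("S3", "CAAGTA"),
    BarcodeSpec("S4", "GTTCAT"),
]


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        sequence_length=100_000,
        reads_per_sample=10_000,
        undigested_fraction=0.1,
        self_ligation_fraction=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_profile(small_config, small_reference):
    return build_profile(
        small_reference.fragment_map, small_config, "A", small_reference.bait
    )


def simulate_lane(config, reference, profile, barcodes, shuffle_seed=None):
    """All samples' reads (optionally shuffled as a lane) plus joint truth."""
    import pandas as pd

    all_reads, truths = [], []
    for spec in barcodes:
        reads, truth = simulate_reads(
            reference, reference.fragment_map, profile, spec, config
        )
        all_reads.extend(reads)
        truths.append(truth)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(all_reads))
        all_reads = [all_reads[i] for i in order]
    return all_reads, pd.concat(truths, ignore_index=True)


def run_pipeline(config, reference, reads, barcodes, **kwargs):
    return process_library(
        reads,
        barcodes,
        reference.sequence,
        reference.fragment_map,
        reference.bait,
        reference.bait_end_sequence(config.primary_motif),
        primary_motif=config.primary_motif,
        **kwargs,
    )
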