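import numpy as np
import pytest

from netcontrast.cohort import NodeTable, build_node_table
from netcontrast.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_node_table() -> NodeTable:
    """32 nodes: 3 cortical networks x 10 + 2 subcortical, both hemispheres."""
    cortical = [
        (hemi, f"Net{k}", f"N{k}_{i}")
        for hemi in ("left", "right")
        for k in range(3)
        for i in range(5)
    ]
    subcortical = [("left", "Amygdala"), ("right", "Amygdala")]
    return build_node_table(cortical, subcortical)


@pytest.fixture(scope="session")
def small_cohort(small_node_table):
    """20 participants over 4 datasets with a planted Net1 effect."""
    config = SyntheticConfig(
        partition=small_node_table,
        dataset_sizes=(5, 5, 5, 5),
        effect_delta=0.15,
        affected_network="Net1",
        sigma_noise=0.05,
        seed=7,
    )
    records, truth, manifest = generate_cohort(config)
    return config, records, truth, manifest
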