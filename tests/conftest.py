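import numpy as np
import pandas as pd
import pytest

from strokecast import SimulationConfig, build_toy_atlas, simulate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    """20-region atlas on a small grid, enough for exact-arithmetic tests."""
    return build_toy_atlas(n_regions=20, atlas_shape=(32, 24, 24), voxel_size_mm=0.25, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete cohort (12 MCAO + 3 sham) with ground truth."""
    cfg = SimulationConfig(
        master_seed=11,
        n_animals=12,
        n_sham=3,
        atlas_shape=(32, 24, 24),
        n_regions=20,
        n_informative=5,
    )
    return simulate_cohort(cfg)


def random_label_volume(rng, shape=(20, 20, 20), n_regions=6):
    """Random labelled volume where every region id 1..n is present."""
    labels = rng.integers(0, n_regions + 1, size=shape).astype(np.int32)
    for rid in range(1, n_regions + 1):  # guarantee presence
        labels.flat[rid] = rid
    return labels


def ontology_for(labels):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    return pd.DataFrame(
        {
            "acronym": [f"R{i}" for i in ids],
            "name": [f"region {i}" for i in ids],
            "hemisphere": ["L" if i % 2 else "R" for i in ids],
            "structure_class": ["core" if i % 2 else "shell" for i in ids],
        },
        index=pd.Index(ids, name="region_id"),
    )
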