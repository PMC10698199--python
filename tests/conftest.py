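import numpy as np
import pandas as pd
import pytest

from hippoparc.io import LabelAtlas, ParcelTable, SeedMask, UptakeVolume
from hippoparc.synth import SyntheticConfig, generate_cohort


def make_label_table(labels, division="cortex", hemisphere="L"):
    return pd.DataFrame(
        {
            "name": [f"region_{l}" for l in labels],
            "division": division,
            "hemisphere": hemisphere,
        },
        index=pd.Index(labels, name="label"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast planted cohort: 40 subjects, 3 clusters over 60 voxels, 24 parcels."""
    cfg = SyntheticConfig(
        n_subjects=40, n_parcels=24, n_seed_voxels=60, k_true=3, loading=1.0,
        noise_sd=0.5, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def affine2mm():
    aff = np.diag([2.0, 2.0, 2.0, 1.0])
    aff[:3, 3] = -20.0
    return aff


@pytest.fixture
def uniform_volume(affine2mm):
    return UptakeVolume(grid=np.full((10, 10, 10), 5.0), affine=affine2mm, subject_id="s1")


@pytest.fixture
def box_mask(affine2mm):
    grid = np.zeros((10, 10, 10), dtype=bool)
    grid[2:5, 2:5, 2:5] = True
    return SeedMask(grid=grid, affine=affine2mm)
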