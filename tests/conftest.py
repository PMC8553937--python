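import numpy as np
import pytest

from catiam.preprocessing import SiteData


@pytest.fixture
def toy_sites():
    """Three hand-built sites exercising every data configuration."""
    return [
        SiteData(site_id=0, y=np.array([1.0, 2.0]), u=np.array([0.0]), w=3,
                 expert_occupancy="present", covariates={"imd": 2.0, "popdens": 0.5},
                 study_area="A"),
        SiteData(site_id=1, y=np.array([0.0]), u=np.array([1.0, 1.0]), w=0,
                 expert_occupancy="absent", covariates={"imd": 7.0, "popdens": -1.0},
                 study_area="A"),
        SiteData(site_id=2, y=np.array([2.0]), u=np.array([]), w=None,
                 expert_occupancy="unknown", covariates={"imd": 5.0, "popdens": 0.0},
                 study_area="B"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
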