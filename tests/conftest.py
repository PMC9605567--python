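import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import harmoz

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_cohort():
    """A compact simulated cohort (all five groups, 6 ROIs) shared by
    integration-style tests."""
    cfg = harmoz.default_config(n_rois=6)
    for name, g in cfg.groups.items():
        g.size = {"NC_3T": 160, "NC_1.5T": 60, "sMCI": 30, "pMCI": 30, "AD": 40}[name]
    subjects, volumes, truth = harmoz.simulate_cohort(cfg, seed=101)
    return subjects, volumes, truth


@pytest.fixture
def nc_reference(small_cohort):
    """NC-only volume table + records from the small cohort."""
    subjects, volumes, _ = small_cohort
    nc = [s for s in subjects if s.group == harmoz.Group.NC]
    ids = {s.subject_id for s in nc}
    rows = [i for i, sid in enumerate(volumes.subject_ids) if sid in ids]
    vnc = harmoz.VolumeTable(
        [volumes.subject_ids[i] for i in rows],
        list(volumes.roi_names),
        volumes.volumes[rows],
    )
    return nc, vnc
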