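import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rarecnv as rc
from rarecnv.simulate import synthesize_probe_map

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_region():
    """A 3-probe loss region (full-span regime) with flank probes."""
    region = rc.RegionDefinition("r_small", "chr1", 1_000_000, 1_030_000,
                                 "loss", 200_000)
    pm = synthesize_probe_map([region], {"r_small": 3})
    return region, pm


@pytest.fixture(scope="session")
def merge_region():
    """A 28-probe loss region (merge-mode regime)."""
    region = rc.RegionDefinition("r_merge", "chr2", 5_000_000, 5_220_000,
                                 "loss", 200_000)
    pm = synthesize_probe_map([region], {"r_merge": 28})
    return region, pm


@pytest.fixture(scope="session")
def candidate_set():
    regions, pm = rc.candidate_region_set()
    return regions, pm


def make_phenotypes(n_case=0, n_control=0, n_pop=0, bmi_case=35.0,
                    bmi_control=22.0, bmi_pop=24.0):
    recs = []
    for i in range(n_case):
        recs.append(rc.SampleRecord(f"case_{i}", "cc_child",
                                    "case_obese_child", "M", 10, bmi_case))
    for i in range(n_control):
        recs.append(rc.SampleRecord(f"ctrl_{i}", "cc_child",
                                    "control_child", "F", 10, bmi_control))
    for i in range(n_pop):
        recs.append(rc.SampleRecord(f"pop_{i}", "population",
                                    "population", "M", 31, bmi_pop))
    return recs
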