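import numpy as np
import pytest

import nursetag as nt

LONG_DIVE = nt.DiveSpec(surface_s=45.0, descent_rate=0.5, max_depth=60.0,
                        bottom_s=180.0, ascent_rate=1.0)


@pytest.fixture(scope="session")
def sim_config():
    """Small, fast deployment: 3 long dives, one mid-descent nursing event."""
    return nt.SimConfig(seed=11, fs_hi=40.0, dive_plan=(LONG_DIVE,) * 3,
                        nursing_events=((100.0, 27.0),))


@pytest.fixture(scope="session")
def sim_deployment(sim_config):
    return nt.simulate_deployment(sim_config, "sim-01", "calf")


@pytest.fixture(scope="session")
def processed(sim_deployment):
    record, _ = sim_deployment
    return nt.process_record(record)


@pytest.fixture(scope="session")
def phase_table(processed):
    return nt.build_phase_table(processed.depth, processed.fs,
                                t0=processed.record.t0)


def flat_record(deployment_id="flat-01", role="calf", duration_s=1200.0,
                fs=10.0):
    """Minimal all-surface record for sampler unit tests."""
    n = int(duration_s * fs)
    acc = np.tile([0.0, 0.0, -9.81], (n, 1))
    return nt.TagRecord(deployment_id=deployment_id, role=role, fs=fs,
                        acc=acc, depth=np.zeros(n))
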