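import numpy as np
import pytest

from tcmdbs import ProtocolSpec, run_protocol

#: Desk-scale replication of the stimulation battery: 10 repetitions per
#: protocol (the full study uses 100), full-length 12 s runs.
BATTERY_PROTOCOLS = ("off", "cdbs20", "cdbs130", "adbs", "bdbs", "bdbs_x5")
BATTERY_REPS = 10
BATTERY_BASE_SEED = 1


@pytest.fixture(scope="session")
def battery():
    """Metrics tables for the protocol battery, keyed by protocol name."""
    tables = {}
    for name in BATTERY_PROTOCOLS:
        spec = ProtocolSpec(name, repetitions=BATTERY_REPS, base_seed=BATTERY_BASE_SEED)
        table = run_protocol(spec)
        assert (table["error"] == "").all(), table["error"].tolist()
        tables[name] = table
    return tables


def median_attenuation(table):
    return float(np.median(table["attenuation"]))
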