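import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from asnscreen.intake import ProteinRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# the packaged reference-table loader warns about the ED-formula discrepancy
# on every load; keep test output readable
logging.getLogger("asnscreen.screening").setLevel(logging.ERROR)


def make_record(seq: str, rid: str = "P1") -> ProteinRecord:
    return ProteinRecord(id=rid, description=f"{rid} test", sequence=seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_protein(rng) -> ProteinRecord:
    seq = "".join(
        np.random.default_rng(7).choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60)
    )
    return make_record(seq, "RAND1")
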