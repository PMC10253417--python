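import numpy as np
import pytest

from aepkit import scattering as sc
from aepkit.records import AEPRecord
from aepkit.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def abr_network():
    return sc.build_network(**sc.ABR_CONFIG)


@pytest.fixture(scope="session")
def amlr_network():
    return sc.build_network(**sc.AMLR_CONFIG)


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-effect cohort reused by several read-only tests."""
    return generate_cohort(CohortConfig(n_patients=30, seed=11))


@pytest.fixture
def abr_record():
    t = np.arange(450) / 30000 * 1000
    x = (0.30 * np.exp(-((t - 1.6) ** 2) / (2 * 0.25 ** 2))
         + 0.30 * np.exp(-((t - 3.9) ** 2) / (2 * 0.25 ** 2))
         + 0.45 * np.exp(-((t - 5.6) ** 2) / (2 * 0.25 ** 2)))
    return AEPRecord(record_id="r-abr", patient_id="p0", ear="left",
                     subtype="ABR", fs_hz=30000.0, samples=x)


@pytest.fixture
def amlr_record():
    t = np.arange(450) / 3000 * 1000
    x = (-0.8 * np.exp(-((t - 18.0) ** 2) / 32.0)
         + 1.0 * np.exp(-((t - 30.0) ** 2) / 32.0)
         - 0.7 * np.exp(-((t - 42.0) ** 2) / 32.0)
         + 0.6 * np.exp(-((t - 55.0) ** 2) / 32.0))
    return AEPRecord(record_id="r-amlr", patient_id="p0", ear="right",
                     subtype="AMLR", fs_hz=3000.0, samples=x)
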