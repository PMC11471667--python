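import numpy as np
import pytest

from petbench.phantom import generate_patient, simulate_study
from petbench.types import AcquisitionMeta, Ellipsoid, PhantomSpec, Sphere


@pytest.fixture
def meta():
    """79 kg patient on the 7 MBq/kg protocol, no decay delay."""
    return AcquisitionMeta(weight=79.0, total_dose=553.0, delay=0.0,
                           time_per_bed=90.0)


@pytest.fixture
def small_spec():
    """Body + one clearly-retained lesion on a small grid."""
    return PhantomSpec(
        shape=(24, 48, 48),
        organs=(Ellipsoid((39.0, 65.0, 65.0), (36.0, 55.0, 55.0), 1.0),),
        lesions=(Sphere((39.0, 65.0, 65.0), 20.0, 4.0),),
    )


@pytest.fixture
def small_study(small_spec, meta):
    rng = np.random.default_rng(7)
    return simulate_study(small_spec, meta, rng)


def _make_split(name, n, seed0, template):
    out = []
    for i in range(n):
        rng = np.random.default_rng(seed0 + i)
        out.append(generate_patient(template, rng, patient_id=f"{name}_{i}"))
    return out


@pytest.fixture(scope="session")
def tiny_dataset():
    """Desk-scale in-memory dataset: 6/2/2 patients on 40x64x64 grids."""
    template = PhantomSpec(shape=(40, 64, 64))
    return {
        "train": _make_split("train", 6, 100, template),
        "val": _make_split("val", 2, 200, template),
        "test": _make_split("test", 2, 300, template),
    }
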