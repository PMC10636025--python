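import numpy as np
import pytest

from lymphspect import PhantomSpec, generate_phantom, run_patient
from lymphspect.phantom import RegionDbfSpec


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0


@pytest.fixture(scope="session")
def affected_phantom():
    """Default-noise affected limb: HP 0.30 in both regions, a distal DBF
    rim, proximal node visible, +20% volume."""
    spec = PhantomSpec(
        hp_fraction_target={"proximal": 0.30, "distal": 0.30},
        dbf={"proximal": RegionDbfSpec(present=False),
             "distal": RegionDbfSpec(present=True)},
        proximal_ln_visible=True,
        intermediate_ln_visible=False,
        ducts_visible=False,
        ct_volume_diff_percent=20.0,
        seed=202,
    )
    ct, spect, truth = generate_phantom(spec)
    return spec, ct, spect, truth


@pytest.fixture(scope="session")
def unaffected_phantom():
    spec = PhantomSpec(seed=203)  # defaults: no HP, no DBF, no inflation
    ct, spect, truth = generate_phantom(spec)
    return spec, ct, spect, truth


@pytest.fixture(scope="session")
def patient_result(affected_phantom, unaffected_phantom):
    """Full chain run once on the session phantoms, masks retained."""
    _, ct_a, spect_a, truth_a = affected_phantom
    _, ct_u, _, _ = unaffected_phantom
    return run_patient(
        ct_a, spect_a, ct_u,
        visibility={"proximal_ln": True, "intermediate_ln": False, "ducts": False},
        patient_id="fixture",
        exclusion_mask=truth_a.exclusion_mask,
        keep_masks=True,
    )
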