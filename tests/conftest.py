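"""Shared fixtures: phantom geometries and (expensive) registration runs.

Phantom studies run at 96x96x40 voxels / 2x2x3 mm so the full suite stays
fast; the registration schedules themselves are the package defaults.
"""

import numpy as np
import pytest

from tomoreg.image import extract_body_mask, mask_background
from tomoreg.phantom import (DeformationSpec, PhantomSpec,
                             apply_synthetic_deformation,
                             generate_thorax_phantom)
from tomoreg.pipeline import PhantomScenario, run_phantom_scenario

SMALL = dict(shape=(96, 96, 40), spacing=(2.0, 2.0, 3.0))
TINY = dict(shape=(80, 80, 28), spacing=(2.4, 2.4, 3.6))

SCENARIO_DEFS = {
    "mediastinal_shift": dict(amplitude_mm=10.0),
    "atelectasis": dict(volume_change_percent=25.0, side="left"),
    "pleural_effusion": dict(amplitude_mm=10.0, side="right"),
    "body_shrink": dict(amplitude_mm=6.0),
    "smooth_random": dict(amplitude_mm=12.0),
}


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL)


@pytest.fixture(scope="session")
def phantom_pair(small_spec):
    """Clean kVCT phantom and its identity ground truth."""
    return generate_thorax_phantom(small_spec)


@pytest.fixture(scope="session")
def preprocessed_phantom(phantom_pair):
    """(masked image, body mask) of the small phantom."""
    img, _ = phantom_pair
    body = extract_body_mask(img)
    return mask_background(img, body), body


@pytest.fixture(scope="session")
def atelectasis_pair(phantom_pair):
    img, truth = phantom_pair
    d = DeformationSpec(mode="atelectasis", volume_change_percent=25.0,
                        side="left", seed=1)
    return apply_synthetic_deformation(img, truth, d)


def _run(mode, seed=1):
    sc = PhantomScenario(mode, phantom=PhantomSpec(**SMALL),
                         deformation=DeformationSpec(mode=mode, seed=1,
                                                     **SCENARIO_DEFS[mode]),
                         fov_z_mm=90.0)
    report, result, truth = run_phantom_scenario(sc, seed=seed)
    return {"report": report, "result": result, "truth": truth}


@pytest.fixture(scope="session")
def scenario_runs():
    """One full registration study per anatomical-change mode."""
    return {mode: _run(mode) for mode in SCENARIO_DEFS}
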