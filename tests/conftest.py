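"""Shared fixtures: catalog and a scaled-range default phantom simulation.

The session phantom keeps the default scene (grid, regions, species levels,
drift, noise, seed) but restricts the acquisition range to m/z 205-235 —
covering the drug/isobar cluster at 210, the dehydrated-drug adducts at
214/230 and the lock mass at 230.946 — so the full pipeline runs in seconds.
"""

from dataclasses import replace

import pytest
from hypothesis import settings

from bpamsi import (
    ROI,
    default_catalog,
    default_phantom_config,
    recalibrate_dataset,
    simulate_dataset,
)
from bpamsi.calibrate import catalog_lock

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def by_name(catalog):
    return {s.name: s for s in catalog}


@pytest.fixture(scope="session")
def phantom_cfg():
    return replace(default_phantom_config(seed=1), mz_range=(205.0, 235.0))


@pytest.fixture(scope="session")
def sim(phantom_cfg):
    return simulate_dataset(phantom_cfg)


@pytest.fixture(scope="session")
def lock():
    return catalog_lock("[DHB-H+2K]+")


@pytest.fixture(scope="session")
def recal(sim, lock):
    """(recalibrated dataset, calibration report) for the session phantom."""
    return recalibrate_dataset(sim.dataset, lock, scope="pixel")


@pytest.fixture(scope="session")
def tumor_roi(sim):
    return ROI.from_mask(sim.masks["tumor"], "tumor")


@pytest.fixture(scope="session")
def cortex_roi(sim):
    return ROI.from_mask(sim.masks["cortex"], "cortex")
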