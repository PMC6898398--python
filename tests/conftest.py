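"""Shared fixtures: probes with and without noise, simple scenes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import sicmph as s

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_probe() -> s.Probe:
    return s.Probe.double_barrel().calibrated()


@pytest.fixture(scope="session")
def noiseless_probe() -> s.Probe:
    probe = s.Probe.double_barrel()
    return dataclasses.replace(
        probe,
        sensor=dataclasses.replace(probe.sensor, noise_rms=0.0),
        feedback=dataclasses.replace(probe.feedback, noise_fraction=0.0),
    ).calibrated()


@pytest.fixture(scope="session")
def noiseless_sensor() -> s.SensorModel:
    return s.SensorModel(noise_rms=0.0)


def make_flat_scene(z0: float = 2e-6, bulk_pH: float = 7.4,
                    extent=(5e-6, 5e-6)) -> s.Scene:
    """Flat substrate at height ``z0``, uniform pH, no sources."""
    medium = s.unbuffered_medium(bulk_pH)
    ground_truth = s.PhField(medium=medium, sources=())

    def topo(x, y):
        z = np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, z0)
        return z if z.ndim else float(z0)

    def mask_fn(x, y):
        return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape,
                        dtype=bool)

    return s.Scene(topography=topo, sources=(), medium=medium,
                   ground_truth=ground_truth, mask_fn=mask_fn, seed=0,
                   extent=extent, transport_mode="free_proton")


@pytest.fixture()
def flat_scene() -> s.Scene:
    return make_flat_scene()


@pytest.fixture(scope="session")
def artefact_scene() -> s.Scene:
    """Active H+ point source above a flat substrate, buffered medium."""
    return s.make_delivery_pipette_scene(
        position=(2e-6, 2e-6, 0.5e-6), medium=s.quarter_hbss_medium(),
        target_dpH=-0.3, target_r=1e-6, extent=(4e-6, 4e-6))


@pytest.fixture(scope="session")
def artefact_scene_off() -> s.Scene:
    """Same geometry with the delivery voltage retained (source off)."""
    return s.make_delivery_pipette_scene(
        position=(2e-6, 2e-6, 0.5e-6), medium=s.quarter_hbss_medium(),
        target_dpH=-0.3, target_r=1e-6, extent=(4e-6, 4e-6),
        gate=((1e9, 2e9),))
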