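"""Shared fixtures: small seeded phantoms and scans reused across modules."""

import numpy as np
import pytest

import phasetomo as pt


@pytest.fixture(scope="session")
def beam25():
    return pt.BeamSpec(25.0)


@pytest.fixture(scope="session")
def cord_phantom():
    """256-px cord phantom; somata count reduced to fit the smaller grid."""
    return pt.make_cord_phantom(grid_px=256, seed=1, n_somata=4)


@pytest.fixture(scope="session")
def clean_scan(cord_phantom):
    """Noiseless absorption-contrast scan (PD = 0, no artefacts)."""
    geom = pt.ScanGeometry(pt.BeamSpec(25.0), pt.DetectorSpec(256, 1, 1.625),
                           0.0, 360)
    art = pt.ArtefactConfig(photon_noise=False, flat_gradient=0.0)
    return pt.simulate_scan(cord_phantom, geom, art, seed=3)


@pytest.fixture(scope="session")
def noisy_scan(cord_phantom):
    """Photon-noise scan at the 85%-saturation operating point (PD = 0)."""
    geom = pt.ScanGeometry(pt.BeamSpec(25.0), pt.DetectorSpec(256, 1, 1.625),
                           0.0, 720)
    return pt.simulate_scan(cord_phantom, geom, pt.ArtefactConfig(), seed=9)


@pytest.fixture(scope="session")
def clean_recon(clean_scan):
    return pt.reconstruct_scan(clean_scan, suppress_rings_flag=False)
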