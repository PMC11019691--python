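"""Shared fixtures: one desk-scale optical configuration and reusable
simulated acquisitions (session scoped, since the forward model is the
expensive part of most tests)."""

import numpy as np
import pytest

from mfsim import (
    CameraConfig,
    EmitterSet,
    IlluminationPattern,
    MultifocusConfig,
    OpticalConfig,
    make_sheet_phantom,
    rasterize_emitters,
    simulate_acquisition,
    simulate_widefield_zscan,
)
from mfsim.registration import calibrate_tile_map

TILE = 128
JITTER = {0: (2, -1), 1: (-3, 0), 2: (1, 1), 4: (0, 2), 5: (-1, -2), 6: (2, 2)}


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def camera():
    return CameraConfig(frame_px=(3 * TILE + 40, 3 * TILE + 40))


@pytest.fixture(scope="session")
def multifocus():
    return MultifocusConfig(tile_px=TILE, jitter=JITTER)


@pytest.fixture(scope="session")
def bead_positions(optics):
    """Nine well-separated beads on the coverslip plane (z = 0)."""
    from mfsim import make_bead_field

    px = optics.px_sample
    field = make_bead_field(
        9, ((TILE - 24) * px, (TILE - 24) * px, 1.0), min_sep=1500.0, seed=5
    )
    pos = field.positions + np.array([12 * px, 12 * px, 0.0])
    pos[:, 2] = 0.0
    return pos


@pytest.fixture(scope="session")
def bead_phantom(optics, bead_positions):
    px = optics.px_sample
    return rasterize_emitters(
        EmitterSet(bead_positions, brightness=20000.0), (1, TILE, TILE), (132.0, px, px)
    )


@pytest.fixture(scope="session")
def bead_acquisition(bead_phantom, optics, multifocus, camera):
    """Noisy three-beam bead acquisition with jittered tiles."""
    return simulate_acquisition(
        bead_phantom, IlluminationPattern(), optics, multifocus, camera, seed=1
    )


@pytest.fixture(scope="session")
def bead_tile_map(bead_phantom, optics, multifocus, camera):
    scan = simulate_widefield_zscan(
        bead_phantom, optics, multifocus, camera, n_steps=9, zstep_nm=264.0, seed=2
    )
    return calibrate_tile_map(scan)


@pytest.fixture(scope="session")
def noiseless_bead_acquisition(bead_phantom, optics, multifocus, camera):
    return simulate_acquisition(
        bead_phantom, IlluminationPattern(), optics, multifocus, camera,
        seed=1, noise=False,
    )


@pytest.fixture(scope="session")
def sheet_phantom(optics):
    """Two perforated sheets: one at the focus, one 792 nm above."""
    px = optics.px_sample
    ph = make_sheet_phantom(
        (17, TILE, TILE), (132.0, px, px), z_planes_nm=(8 * 132.0, 14 * 132.0), seed=11
    )
    ph.volume *= 300.0
    return ph


@pytest.fixture(scope="session")
def plain_multifocus():
    return MultifocusConfig(tile_px=TILE)


@pytest.fixture(scope="session")
def sheet_tile_map(sheet_phantom, optics, plain_multifocus, camera):
    scan = simulate_widefield_zscan(
        sheet_phantom, optics, plain_multifocus, camera, n_steps=9, zstep_nm=264.0, seed=2
    )
    return calibrate_tile_map(scan)
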