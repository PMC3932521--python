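"""Shared fixtures: small synthetic filament datasets with known truth.

Everything is generated programmatically at session scope so the expensive
volumes/stacks are built once per run.
"""

import numpy as np
import pytest

from helixforge import heligeom as hg
from helixforge import synthgen as sg
from helixforge import ihrsr


CARD = hg.HelicalSymmetry(-53.6, 16.8, 3)
MINI_VOXEL = 4.52
MINI_BOX = 64


@pytest.fixture(scope="session")
def card_sym():
    return CARD


@pytest.fixture(scope="session")
def card_tpl():
    return sg.card_template()


@pytest.fixture(scope="session")
def card_volume(card_sym, card_tpl):
    """64^3 CARD-like filament volume at 4.52 A/voxel."""
    return sg.build_volume(card_sym, card_tpl, radius=32.0, grid=MINI_BOX, voxel=MINI_VOXEL)


@pytest.fixture(scope="session")
def card_reference(card_volume, card_sym):
    """Symmetrized reference for alignment tests."""
    return ihrsr.impose_symmetry(card_volume, card_sym)


@pytest.fixture(scope="session")
def clean_stack(card_sym, card_tpl):
    """36 noise-free segments with moderate orientation jitter."""
    return sg.simulate_segments(
        card_sym, card_tpl, n_filaments=4, length=121, box=MINI_BOX, overlap=0.9,
        noise_sigma=0.0, seed=3, pixel=MINI_VOXEL, radius=32.0,
        tilt_jitter=6.0, inplane_jitter=4.0, shift_jitter_px=3.0,
    )


@pytest.fixture(scope="session")
def noisy_stack(card_sym, card_tpl):
    """126 segments at SNR 0.5 — enough signal for a mini refinement at
    this 64-px scale (overlapping segments share filament noise, so the
    effective number of independent noise realizations is the filament
    count)."""
    return sg.simulate_segments(
        card_sym, card_tpl, n_filaments=14, length=121, box=MINI_BOX, overlap=0.9,
        snr=0.5, seed=7, pixel=MINI_VOXEL, radius=32.0,
        tilt_jitter=4.0, inplane_jitter=3.0, shift_jitter_px=2.0,
    )


@pytest.fixture(scope="session")
def mini_align_params():
    return ihrsr.AlignParams(
        azimuth_step=4.0, azimuth_max=120.0, tilt_range=6.0, tilt_step=2.0,
        inplane_range=4.0, inplane_step=2.0, max_shift_px=4, n_phase=5,
    )


def lattice_equivalent_azimuth_error(true_az, est_az, sym):
    """Smallest azimuth discrepancy modulo the helical lattice relations
    (an axial phase shift of one rise re-labels the azimuth by one twist,
    and the C_n rotation by 360/n)."""
    period = 360.0 / sym.n_start
    best = np.full(len(true_az), np.inf)
    for k in (-2, -1, 0, 1, 2):
        d = (np.asarray(true_az) - np.asarray(est_az) + k * sym.twist) % period
        d = np.minimum(d, period - d)
        best = np.minimum(best, np.abs(d))
    return best
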