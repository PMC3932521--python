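"""Canonical study conditions for the bundled filament systems.

These dictionaries are the single source of the desk-scale protocol
parameters used by the command-line pipelines, the acceptance script and
the test suite: a three-start left-handed CARD-like filament
(twist -53.6 deg, rise 16.8 A), its peripheral-decorated variant
(twist -52.9 deg, rise 16.9 A, fragmented density ~15 A outside the
core), and the indexing condition with rise 16.7 A matching the measured
meridional layer line.
"""

from __future__ import annotations

from .heligeom import HelicalSymmetry
from .ihrsr import AlignParams
from .synthgen import card_template, decorated_template

__all__ = [
    "CARD_SYMMETRY",
    "DPROTM_SYMMETRY",
    "INDEXING_SYMMETRY",
    "card_study",
    "dprotm_study",
    "indexing_study",
    "desk_align_params",
]

CARD_SYMMETRY = HelicalSymmetry(twist=-53.6, rise=16.8, n_start=3)
DPROTM_SYMMETRY = HelicalSymmetry(twist=-52.9, rise=16.9, n_start=3)
INDEXING_SYMMETRY = HelicalSymmetry(twist=-53.6, rise=16.7, n_start=3)


def card_study(seed: int = 11) -> dict:
    """Desk-scale IHRSR recovery study on the CARD-like filament:
    ~300 segments, 100 px box at 4.52 A/px (a 2x-binned analogue of
    200 px at 2.26 A), SNR 0.2, strand radius 32 A."""
    return dict(
        sym=CARD_SYMMETRY,
        template=card_template(),
        n_filaments=30,
        length=190,
        box=100,
        overlap=0.9,
        snr=0.2,
        pixel=4.52,
        radius=32.0,
        seed=seed,
    )


def dprotm_study(seed: int = 12) -> dict:
    """As :func:`card_study` but with the peripheral-decorated template
    and the decorated-filament symmetry."""
    d = card_study(seed)
    d.update(sym=DPROTM_SYMMETRY, template=decorated_template())
    return d


def indexing_study(seed: int = 5) -> dict:
    """Layer-line indexing condition: 128 px box at 2.26 A/px, rise
    16.7 A, enough segments for a clean summed power spectrum."""
    return dict(
        sym=INDEXING_SYMMETRY,
        template=card_template(),
        n_filaments=24,
        length=218,
        box=128,
        overlap=0.9,
        snr=0.5,
        pixel=2.26,
        radius=32.0,
        seed=seed,
    )


def desk_align_params(n_start: int = 3) -> AlignParams:
    """Projection-matching grid for the desk-scale refinements: 4 deg
    azimuth over one C_n sector, out-of-plane tilt to 15 deg in 2 deg
    steps, in-plane +-6 deg in 2 deg steps, +-8 px shifts."""
    return AlignParams(
        azimuth_step=4.0,
        azimuth_max=360.0 / n_start,
        tilt_range=15.0,
        tilt_step=2.0,
        inplane_range=6.0,
        inplane_step=2.0,
        max_shift_px=8,
        n_phase=5,
    )


IHRSR_INIT = HelicalSymmetry(twist=-50.0, rise=15.5, n_start=3)
IHRSR_DEFAULTS = dict(max_iters=30, cylinder_diameter=90.0, search_bounds=(2.0, 1.2))
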