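"""Helical symmetry algebra and lattice geometry.

A helical filament is described by the azimuthal rotation (twist, degrees)
and axial translation (rise, Angstrom) relating consecutive subunits within
one strand, plus the number of intertwined strands (``n_start``).  The sign
of the twist encodes chirality: by the package convention, positive twist
means the azimuth increases with +z in a right-handed frame (a right-handed
helix), so a left-handed filament such as the MAVS CARD assembly carries
twist = -53.6 deg.

All angles are degrees; all lengths are Angstrom unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "HelicalSymmetry",
    "SubunitPlacement",
    "lattice_stats",
    "place_subunits",
    "mirror",
    "stripe_span",
    "stripe_angle",
]


def _normalize_angle(a: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class HelicalSymmetry:
    """Per-subunit helical symmetry.

    Parameters
    ----------
    twist:
        Signed azimuthal rotation per subunit, degrees, normalized to
        (-180, 180].  Negative = left-handed.
    rise:
        Axial translation per subunit, Angstrom, > 0.
    n_start:
        Number of strands related by an n-fold rotation about the axis.
    """

    twist: float
    rise: float
    n_start: int = 1

    def __post_init__(self) -> None:
        t = _normalize_angle(float(self.twist))
        object.__setattr__(self, "twist", t)
        if not (0.0 < abs(self.twist) <= 180.0):
            raise ValueError(f"twist must satisfy 0 < |twist| <= 180, got {self.twist}")
        if not (self.rise > 0):
            raise ValueError(f"rise must be positive, got {self.rise}")
        if not (isinstance(self.n_start, (int, np.integer)) and self.n_start >= 1):
            raise ValueError(f"n_start must be an integer >= 1, got {self.n_start}")

    @property
    def handedness(self) -> str:
        return "right" if self.twist > 0 else "left"

    @property
    def subunits_per_turn(self) -> float:
        return 360.0 / abs(self.twist)

    @property
    def pitch(self) -> float:
        """Axial length of one full turn of a strand, Angstrom."""
        return self.subunits_per_turn * self.rise


@dataclass(frozen=True)
class SubunitPlacement:
    """One subunit on the helical lattice.

    ``position`` is the strand-radius point in Angstrom (x, y, z);
    ``azimuth`` is reported mod 360 in [0, 360).
    """

    position: np.ndarray
    azimuth: float
    layer: int
    strand: int


def lattice_stats(sym: HelicalSymmetry, length: Optional[float] = None) -> dict:
    """Summary geometry of the helical lattice.

    Returns ``subunits_per_turn`` (360/|twist|), ``pitch`` (Angstrom per
    full turn of one strand) and, when a filament ``length`` in Angstrom is
    given, ``count``: the total number of subunits over that length summed
    across all strands, rounded half-up per layer.
    """
    out = {"subunits_per_turn": sym.subunits_per_turn, "pitch": sym.pitch}
    if length is not None:
        if length <= 0:
            raise ValueError(f"length must be positive, got {length}")
        # total across strands, rounded half-up
        out["count"] = math.floor(length / sym.rise * sym.n_start + 0.5)
    return out


def place_subunits(sym: HelicalSymmetry, n_layers: int, radius: float = 1.0) -> list[SubunitPlacement]:
    """Generate the lattice of subunit anchor points.

    Layer ``k`` sits at z = k*rise; strand ``j`` of layer ``k`` has azimuth
    k*twist + j*360/n_start (mod 360).  Returns n_layers * n_start
    placements ordered by (layer, strand).
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    placements = []
    for k in range(n_layers):
        z = k * sym.rise
        for j in range(sym.n_start):
            az = (k * sym.twist + j * 360.0 / sym.n_start) % 360.0
            pos = np.array(
                [radius * math.cos(math.radians(az)),
                 radius * math.sin(math.radians(az)),
                 z]
            )
            placements.append(SubunitPlacement(position=pos, azimuth=az, layer=k, strand=j))
    return placements


def mirror(sym: HelicalSymmetry) -> HelicalSymmetry:
    """The enantiomeric symmetry: twist sign flipped, rise and n_start kept.

    Involution: ``mirror(mirror(s)) == s``.
    """
    return replace(sym, twist=-sym.twist)


def stripe_span(sym: HelicalSymmetry, n_layers: int) -> float:
    """Axial distance in Angstrom spanned by ``n_layers`` lattice layers.

    For the CARD filament geometry (rise 16.8 A) seven layers span
    ~118 A, the distance measurable across stripe patterns on the
    filament surface.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    return n_layers * sym.rise


def stripe_angle(sym: HelicalSymmetry, radius: float) -> float:
    """Exploratory helper: angle (degrees) between surface stripes and the
    helical axis, for the ``n_start``-strand stripe family traced at the
    given radius.

    The stripe family formed by the n_start strands advances axially by
    pitch/1 per turn of each strand; at trace radius r the stripe makes an
    angle atan(2*pi*r / pitch) with the axis.  The value depends on the
    (unknowable from projections) trace radius and is not an acceptance
    surface.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return math.degrees(math.atan2(2.0 * math.pi * radius, sym.pitch))
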