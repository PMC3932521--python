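"""Rigid template docking, handedness determination and model expansion.

A single projection (and hence any map refined from projections alone)
cannot distinguish a helix from its mirror image: the two enantiomorphic
maps fit the images equally well.  Docking a chiral subunit template into
the map and its mirror breaks the tie — only the correctly handed map
accommodates the template's internal geometry.  The margin between the
two docking scores is the confidence of the handedness call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy import ndimage, optimize

from .heligeom import HelicalSymmetry, place_subunits
from ._fourier import rot_x, rot_y, rot_z
from .synthgen import DensityVolume, SubunitTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "DockPose",
    "mirror_volume",
    "dock_template",
    "call_handedness",
    "expand_model",
    "pore_profile",
    "load_pdb_template",
]


@dataclass
class DockPose:
    """Rigid-body pose: intrinsic z-y-z Euler angles (degrees) and a
    translation in Angstrom, with the normalized-correlation score."""

    rotation: tuple[float, float, float]
    translation: np.ndarray
    score: float

    def matrix(self) -> np.ndarray:
        a, b, g = self.rotation
        return rot_z(a) @ rot_y(b) @ rot_z(g)


def mirror_volume(volume: DensityVolume) -> DensityVolume:
    """Reflect through the plane containing the helical axis and the
    first in-plane grid axis (x -> -x), about the center voxel N//2 so
    that mirroring twice is exactly the identity (the boundary column
    wraps; density there is zero for any centered map)."""
    g = np.roll(volume.grid[:, :, ::-1], 1, axis=2).copy()
    return DensityVolume(g, volume.voxel)


def _render_points(template: SubunitTemplate):
    pos = np.array([o for o, _, _ in template.blobs])
    amp = np.array([a for _, a, _ in template.blobs])
    wid = np.array([w for _, _, w in template.blobs])
    return pos, amp, wid


def _sample_map(volume: DensityVolume, pts: np.ndarray) -> np.ndarray:
    """Map values at Angstrom coordinates (N, 3) xyz, origin at center."""
    c = volume.n // 2
    coords = np.stack([pts[:, 2], pts[:, 1], pts[:, 0]]) / volume.voxel + c
    return ndimage.map_coordinates(volume.grid, coords, order=1, mode="constant")


def _pose_score(volume, pos, amp, wid, R, t, probe):
    """Normalized correlation between the rendered template density (the
    full Gaussian mixture — blobs overlap) and the map, evaluated on
    probe points around the transformed blob centers."""
    ctr = pos @ R.T + t
    pts = (ctr[:, None, :] + probe[None, :, :] * wid[:, None, None]).reshape(-1, 3)
    # mixture model: every blob contributes at every probe point
    d2 = np.sum((pts[:, None, :] - ctr[None, :, :]) ** 2, axis=2)  # (npts, nblob)
    model = (np.exp(-d2 / (2 * wid[None, :] ** 2)) * amp[None, :]).sum(axis=1)
    data = _sample_map(volume, pts)
    m0, d0 = model - model.mean(), data - data.mean()
    den = np.linalg.norm(m0) * np.linalg.norm(d0)
    return float(m0 @ d0 / den) if den > 0 else 0.0


_PROBE = None


def _probe_points(n_shell: int = 3) -> np.ndarray:
    """Fixed probe offsets (in blob-sigma units) sampling each blob and
    its surroundings."""
    global _PROBE
    if _PROBE is None:
        g = np.linspace(-1.5, 1.5, n_shell)
        _PROBE = np.array(list(product(g, g, g)))
    return _PROBE


def is_chiral(template: SubunitTemplate, tol: float = 0.99) -> bool:
    """A template is chiral if no proper rotation superposes it onto its
    mirror image (checked by exhaustive rotational scoring of the blob
    model against its reflection)."""
    pos, amp, wid = _render_points(template)
    pos = pos - np.average(pos, axis=0, weights=amp)
    mpos = pos * np.array([-1.0, 1.0, 1.0])

    def cloud_corr(R):
        # correlation of Gaussian mixtures under rotation R of the mirror
        q = mpos @ R.T
        s = 0.0
        for i in range(len(pos)):
            d2 = np.sum((q - pos[i]) ** 2, axis=1)
            ss = wid[i] ** 2 + wid ** 2
            s += np.sum(amp[i] * amp * np.exp(-d2 / (2 * ss)))
        return s

    self_s = None
    best = 0.0
    grid = np.arange(0.0, 360.0, 15.0)
    betas = np.arange(0.0, 181.0, 15.0)
    for a in grid:
        for b in betas:
            for g in grid:
                R = rot_z(a) @ rot_y(b) @ rot_z(g)
                best = max(best, cloud_corr(R))
    # self-overlap reference (mirror of mirror at identity)
    q = pos
    s = 0.0
    for i in range(len(pos)):
        d2 = np.sum((q - pos[i]) ** 2, axis=1)
        ss = wid[i] ** 2 + wid ** 2
        s += np.sum(amp[i] * amp * np.exp(-d2 / (2 * ss)))
    self_s = s
    return best < tol * self_s


def dock_template(
    volume: DensityVolume,
    template: SubunitTemplate,
    coarse_step: float = 15.0,
    fine_step: float = 3.0,
    init_translation: Optional[np.ndarray] = None,
    translation_span: float = 8.0,
) -> DockPose:
    """Exhaustive coarse rotational search plus local refinement of a
    blob template against a map.

    Rotations sample intrinsic z-y-z Euler angles at ``coarse_step``;
    the best pose is refined at ``fine_step`` and its translation
    polished with Nelder-Mead.  Score is normalized correlation between
    the rendered template density and the map around the template
    footprint.
    """
    pos, amp, wid = _render_points(template)
    if np.ptp(np.linalg.norm(pos - pos.mean(axis=0), axis=1)) < 1e-9 and len(pos) <= 1:
        logger.warning("degenerate (spherical) template: pose rotation meaningless")
    probe = _probe_points()
    if init_translation is None:
        init_translation = np.zeros(3)
    t0 = np.asarray(init_translation, dtype=float)

    def rot_grid(step, around=None, span=180.0):
        alphas = np.arange(0.0, 360.0, step)
        betas = np.arange(0.0, 180.1, step)
        gammas = np.arange(0.0, 360.0, step)
        if around is not None:
            a0, b0, g0 = around
            alphas = a0 + np.arange(-span, span + 1e-9, step)
            betas = np.clip(b0 + np.arange(-span, span + 1e-9, step), 0.0, 180.0)
            gammas = g0 + np.arange(-span, span + 1e-9, step)
        return [(a, b, g) for a in alphas for b in betas for g in gammas]

    best = (-2.0, (0.0, 0.0, 0.0))
    for abg in rot_grid(coarse_step):
        R = rot_z(abg[0]) @ rot_y(abg[1]) @ rot_z(abg[2])
        s = _pose_score(volume, pos, amp, wid, R, t0, probe)
        if s > best[0]:
            best = (s, abg)
    for abg in rot_grid(fine_step, around=best[1], span=coarse_step):
        R = rot_z(abg[0]) @ rot_y(abg[1]) @ rot_z(abg[2])
        s = _pose_score(volume, pos, amp, wid, R, t0, probe)
        if s > best[0]:
            best = (s, abg)
    abg = best[1]
    R = rot_z(abg[0]) @ rot_y(abg[1]) @ rot_z(abg[2])

    def neg(t):
        return -_pose_score(volume, pos, amp, wid, R, t, probe)

    res = optimize.minimize(
        neg, t0, method="Nelder-Mead",
        options={"xatol": 0.1, "fatol": 1e-5, "maxiter": 200},
    )
    t_best = res.x if -res.fun >= best[0] else t0
    score = max(-res.fun, best[0])
    return DockPose(rotation=tuple(float(v) for v in abg), translation=np.asarray(t_best), score=float(score))


def call_handedness(
    map_volume: DensityVolume,
    template: SubunitTemplate,
    nominal_hand: str = "left",
    margin_floor: float = 0.01,
    **dock_kwargs,
) -> tuple[str, float]:
    """Determine the map's handedness by docking into it and its mirror.

    A reconstruction from projections carries an arbitrary hand:
    ``nominal_hand`` is the hand the map was reconstructed/imposed with.
    The chiral template is docked into the map and into its mirror; if
    the map as given wins, its nominal hand is confirmed, otherwise the
    opposite hand is called.  Returns ('left' | 'right' | 'undetermined',
    score margin); a margin below ``margin_floor`` is undetermined.
    """
    if nominal_hand not in ("left", "right"):
        raise ValueError("nominal_hand must be 'left' or 'right'")
    if not is_chiral(template):
        raise ValueError("achiral template cannot determine handedness")
    p_orig = dock_template(map_volume, template, **dock_kwargs)
    # the mirror operation moves any initial placement along with the map
    mirr_kwargs = dict(dock_kwargs)
    if mirr_kwargs.get("init_translation") is not None:
        t = np.asarray(mirr_kwargs["init_translation"], dtype=float).copy()
        t[0] = -t[0]
        mirr_kwargs["init_translation"] = t
    p_mirr = dock_template(mirror_volume(map_volume), template, **mirr_kwargs)
    margin = abs(p_orig.score - p_mirr.score)
    if margin < margin_floor:
        return "undetermined", margin
    other = "right" if nominal_hand == "left" else "left"
    return (nominal_hand if p_orig.score > p_mirr.score else other), margin


def expand_model(
    pose: DockPose,
    sym: HelicalSymmetry,
    n_layers: int,
    radius: float = 0.0,
) -> list[np.ndarray]:
    """Apply the helical lattice to a docked pose.

    Returns ``n_layers * n_start`` 4x4 transform matrices; with
    ``n_layers=2`` and a 3-start symmetry this is the six-subunit
    (hexamer) arrangement of two stacked C3 layers.
    """
    placements = place_subunits(sym, n_layers, radius=radius)
    P = np.eye(4)
    P[:3, :3] = pose.matrix()
    P[:3, 3] = pose.translation
    out = []
    for pl in placements:
        T = np.eye(4)
        T[:3, :3] = rot_z(pl.azimuth)
        T[:3, 3] = pl.position if radius > 0 else np.array([0.0, 0.0, pl.position[2]])
        out.append(T @ P)
    return out


def pore_profile(
    volume: DensityVolume,
    threshold: float = 0.5,
) -> tuple[np.ndarray, float, bool]:
    """Axial pore radius profile and minimum pore diameter.

    For each z-slice, the pore radius is the largest radius around the
    axis within which all density stays below ``threshold`` x max(map).
    Returns (per-slice radius in Angstrom, 2 x min over the central half
    of the slices, flag set when the axis itself is above threshold).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    g = volume.grid
    N = volume.n
    c = N // 2
    cut = threshold * g.max()
    y, x = np.meshgrid(np.arange(N) - c, np.arange(N) - c, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2) * volume.voxel
    r_bins = np.arange(0.0, (c - 1) * volume.voxel, volume.voxel)
    radii = np.zeros(N)
    flagged = False
    for iz in range(N):
        sl = g[iz]
        blocked = sl >= cut
        if blocked[c, c]:
            radii[iz] = 0.0
            flagged = True
            continue
        pr = 0.0
        for rb in r_bins[1:]:
            ring = (r >= rb - volume.voxel) & (r < rb)
            if np.any(blocked[ring]):
                break
            pr = rb
        radii[iz] = pr
    central = radii[N // 4: 3 * N // 4]
    min_d = 2.0 * float(central.min()) if len(central) else 0.0
    if min_d == 0.0:
        flagged = True
    return radii, min_d, flagged


def load_pdb_template(path, width: float = 2.0, amplitude: float = 1.0) -> SubunitTemplate:
    """Read atomic coordinates from a PDB file and return a blob template
    (one fixed-width Gaussian per atom, centered coordinates)."""
    pts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                pts.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not pts:
        raise ValueError(f"no atoms found in {path}")
    pts = np.asarray(pts)
    pts -= pts.mean(axis=0)
    return SubunitTemplate(tuple((p, amplitude, width) for p in pts))
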