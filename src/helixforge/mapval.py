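"""Map validation: half-set splitting, volume alignment, Fourier shell
correlation, amplitude correction and the map-vs-data power check.

Resolution is read at FSC = 0.5 between two reconstructions computed from
disjoint halves of the data.  Halves are split at the level of whole
filaments: neighboring segments of one filament overlap by up to 90% and
would leak correlation into both halves if split segment-wise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from ._fourier import cfftn, cifftn, extract_slices, view_matrix
from .synthgen import CTFParams, DensityVolume, SegmentStack, ctf_eval
from .layerlines import PowerSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "FSCCurve",
    "split_halves",
    "align_volumes",
    "fsc_resolution",
    "amplitude_correct",
    "map_power_projections",
]


@dataclass
class FSCCurve:
    """Shell-wise correlation between two volumes."""

    freq: np.ndarray  # 1/Angstrom, strictly increasing
    fsc: np.ndarray   # in [-1, 1]

    def __post_init__(self):
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")


def split_halves(stack: SegmentStack) -> tuple[SegmentStack, SegmentStack]:
    """Split a stack into two filament-disjoint halves of near-equal
    segment counts (greedy balancing over filaments)."""
    fids = stack.records["filament"].to_numpy()
    unique, counts = np.unique(fids, return_counts=True)
    if len(unique) < 2:
        raise ValueError("need at least 2 filaments for an independent split")
    order = np.argsort(-counts)
    tot = [0, 0]
    side = {}
    for i in order:
        s = 0 if tot[0] <= tot[1] else 1
        side[unique[i]] = s
        tot[s] += counts[i]
    mask = np.array([side[f] == 0 for f in fids])
    return stack.subset(np.nonzero(mask)[0]), stack.subset(np.nonzero(~mask)[0])


def align_volumes(
    v1: DensityVolume,
    v2: DensityVolume,
    rot_step: float = 0.5,
    n_phi: int = 720,
) -> tuple[dict, DensityVolume]:
    """Align v2 to v1 over axial rotation and sub-pixel axial shift.

    The correlation surface over (rotation about z, z-shift) is computed
    in one pass from cylindrical-coordinate transforms (FFT over angle and
    z), then the peak is refined by quadratic interpolation and applied to
    v2.  Returns ({'rotation_deg', 'shift_px', 'corr'}, v2_aligned).
    """
    if v1.grid.shape != v2.grid.shape or not math.isclose(v1.voxel, v2.voxel):
        raise ValueError("volumes must share grid and voxel size")
    N = v1.n
    c = N // 2
    radii = np.arange(1.0, c - 1.0)
    phis = np.arange(n_phi) * (2 * np.pi / n_phi)
    rr, pp = np.meshgrid(radii, phis, indexing="ij")
    xs, ys = rr * np.cos(pp) + c, rr * np.sin(pp) + c
    zs = np.arange(N)
    coords = np.stack([
        np.broadcast_to(zs[:, None, None], (N,) + rr.shape).ravel(),
        np.broadcast_to(ys[None], (N,) + rr.shape).ravel(),
        np.broadcast_to(xs[None], (N,) + rr.shape).ravel(),
    ])
    def tocyl(v):
        return ndimage.map_coordinates(v.grid, coords, order=1).reshape(N, len(radii), n_phi)
    c1, c2 = tocyl(v1), tocyl(v2)
    F1 = np.fft.fft(np.fft.fft(c1, axis=0), axis=2)
    F2 = np.fft.fft(np.fft.fft(c2, axis=0), axis=2)
    X = np.einsum("zrm,r,zrm->zm", np.conj(F2), radii, F1)
    surf = np.fft.ifft2(X).real  # (dz, dphi) correlation surface
    iz, ip = np.unravel_index(np.argmax(surf), surf.shape)

    def _sub(v, i, n):
        ym, y0, yp = v[(i - 1) % n], v[i], v[(i + 1) % n]
        d = ym - 2 * y0 + yp
        return 0.5 * (ym - yp) / d if abs(d) > 1e-12 * abs(y0) else 0.0

    dz = iz + _sub(surf[:, ip], iz, N)
    dphi = ip + _sub(surf[iz, :], ip, n_phi)
    if dz > N / 2:
        dz -= N
    if dphi > n_phi / 2:
        dphi -= n_phi
    rot_deg = dphi * 360.0 / n_phi
    norm = math.sqrt(float(np.einsum("zrm,r->", np.abs(F1) ** 2, radii)) *
                     float(np.einsum("zrm,r->", np.abs(F2) ** 2, radii)))
    corr = float(surf[iz, ip]) * N * n_phi / norm if norm > 0 else 0.0
    if abs(rot_deg) < 1e-3 and abs(dz) < 1e-3:
        return {"rotation_deg": 0.0, "shift_px": 0.0, "corr": corr}, v2.copy()

    # apply: rotate about z by rot_deg, shift z by dz voxels
    a = math.radians(rot_deg)
    ca, sa = math.cos(a), math.sin(a)
    M = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    center = np.array([c, c, c], dtype=float)
    offset = center - M @ center
    offset[0] -= dz
    moved = ndimage.affine_transform(v2.grid, M, offset=offset, order=1)
    return {"rotation_deg": rot_deg, "shift_px": float(dz), "corr": corr}, DensityVolume(moved, v2.voxel)


def fsc_resolution(
    v1: DensityVolume,
    v2: DensityVolume,
    threshold: float = 0.5,
) -> tuple[FSCCurve, float, bool]:
    """FSC between two aligned volumes and the resolution at ``threshold``.

    Shells are one Fourier voxel wide; the resolution is 1/frequency of
    the first crossing below the threshold, linearly interpolated between
    shells.  If the curve never crosses, Nyquist is returned with a flag.
    """
    if v1.grid.shape != v2.grid.shape or not math.isclose(v1.voxel, v2.voxel):
        raise ValueError("volumes must share grid and voxel size")
    N = v1.n
    c = N // 2
    F1, F2 = cfftn(v1.grid), cfftn(v2.grid)
    z, y, x = np.indices(F1.shape)
    r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
    shell = np.minimum(r.astype(int), c)
    num = np.bincount(shell.ravel(), (F1 * np.conj(F2)).real.ravel(), minlength=c + 1)
    d1 = np.bincount(shell.ravel(), np.abs(F1).ravel() ** 2, minlength=c + 1)
    d2 = np.bincount(shell.ravel(), np.abs(F2).ravel() ** 2, minlength=c + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = num / np.sqrt(d1 * d2)
    fsc = np.nan_to_num(fsc[: c + 1], nan=0.0)
    freq = np.arange(c + 1) / (N * v1.voxel)
    curve = FSCCurve(freq[1:], fsc[1:])  # drop the DC shell from the curve
    nyquist = 1.0 / (2.0 * v1.voxel)
    below = np.nonzero(fsc[1:] < threshold)[0]
    if len(below) == 0:
        return curve, 1.0 / nyquist, True
    i = below[0] + 1  # first shell below threshold (index into fsc/freq)
    if i == 1:
        return curve, 1.0 / freq[1], False
    f0, f1_ = freq[i - 1], freq[i]
    y0, y1_ = fsc[i - 1], fsc[i]
    fc = f0 + (y0 - threshold) / (y0 - y1_) * (f1_ - f0) if y0 != y1_ else f0
    return curve, 1.0 / fc, False


def amplitude_correct(
    volume: DensityVolume,
    mode: str = "bfactor",
    B: float = -1100.0,
    ctfs: Optional[Sequence[CTFParams]] = None,
    low_pass: float = 9.6,
    envelope_floor: float = 0.1,
) -> DensityVolume:
    """Sharpen or envelope-correct a map, then low-pass filter it.

    ``bfactor`` multiplies radial amplitudes by exp(-B s^2 / 4) (negative
    B sharpens); ``envelope`` divides by the average CTF envelope |CTF|
    of the given parameter list, floored at ``envelope_floor`` of its
    peak.  Both are followed by a cosine-edge low-pass at ``low_pass``
    Angstrom.
    """
    N = volume.n
    c = N // 2
    F = cfftn(volume.grid)
    z, y, x = np.indices(F.shape)
    s = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) / (N * volume.voxel)
    if mode == "bfactor":
        if B == 0:
            raise ValueError("B must be nonzero in bfactor mode")
        F = F * np.exp(-B * s ** 2 / 4.0)
    elif mode == "envelope":
        if not ctfs:
            raise ValueError("envelope mode needs CTF parameters")
        env = np.mean([np.abs(ctf_eval(p, s)) for p in ctfs], axis=0)
        floor = envelope_floor * env.max()
        s_used = s <= (1.0 / low_pass if low_pass else 0.5 / volume.voxel)
        n_floored = int(np.sum((env < floor) & s_used))
        if n_floored:
            logger.info("envelope floored at %d voxels", n_floored)
        F = F / np.maximum(env, floor)
    else:
        raise ValueError(f"unknown amplitude_correct mode {mode!r}")
    if low_pass is not None:
        s_cut = 1.0 / low_pass
        edge = 2.0 / (N * volume.voxel)  # two-voxel cosine edge
        t = np.clip((s - (s_cut - edge)) / (2 * edge), 0.0, 1.0)
        F = F * (0.5 + 0.5 * np.cos(np.pi * t))
    out = cifftn(F).real
    return DensityVolume(out, volume.voxel)


def map_power_projections(volume: DensityVolume, n_orientations: int = 360) -> PowerSpectrum:
    """Summed power spectrum of map projections at ``n_orientations``
    axial rotations — comparable axis-for-axis with the raw-data summed
    power spectrum."""
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    VF = cfftn(volume.grid)
    azs = np.arange(n_orientations) * (360.0 / n_orientations)
    Rs = np.array([view_matrix(a, 0.0, 0.0) for a in azs])
    sl = extract_slices(VF, Rs)
    power = np.mean(np.abs(sl) ** 2, axis=0)
    return PowerSpectrum(power, volume.voxel)
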