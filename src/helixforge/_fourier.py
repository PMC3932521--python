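"""Internal Fourier-space geometry kernels.

Conventions (used package-wide, see docs/methods.md):

* Volumes are numpy arrays indexed ``V[z, y, x]`` with the helical axis
  along z and the origin at the grid center ``N // 2``.
* Images are indexed ``img[v, u]``: ``v`` is the vertical (filament-axis)
  direction, ``u`` horizontal.  At identity orientation ``u -> lab x`` and
  ``v -> lab z``; projection integrates along lab y.
* Orientations are ``R = Ry(inplane) @ Rx(tilt) @ Rz(azimuth)`` applied to
  the volume; a projection's 2D transform is the central slice
  ``F2(ku, kv) = F3(R^T (ku, 0, kv))`` (projection-slice theorem).
* Centered transforms: ``fftshift(fftn(ifftshift(.)))`` so that both the
  real-space origin and DC sit at ``N // 2``.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import fftn, fftshift, ifftn, ifftshift
from scipy.ndimage import map_coordinates

__all__ = [
    "rot_z",
    "rot_x",
    "rot_y",
    "view_matrix",
    "cfft2",
    "cifft2",
    "cfftn",
    "cifftn",
    "extract_slices",
    "insert_slices",
    "shift_phase",
]


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def view_matrix(azimuth: float, tilt: float = 0.0, inplane: float = 0.0) -> np.ndarray:
    """Volume-to-lab rotation for a view (azimuth about z, then out-of-plane
    tilt about lab x, then in-plane rotation about the viewing axis)."""
    return rot_y(inplane) @ rot_x(tilt) @ rot_z(azimuth)


def cfft2(img: np.ndarray) -> np.ndarray:
    return fftshift(np.fft.fft2(ifftshift(img)))


def cifft2(F: np.ndarray) -> np.ndarray:
    return fftshift(np.fft.ifft2(ifftshift(F)))


def cfftn(vol: np.ndarray) -> np.ndarray:
    return fftshift(fftn(ifftshift(vol)))


def cifftn(F: np.ndarray) -> np.ndarray:
    return fftshift(ifftn(ifftshift(F)))


def _slice_freqs(B: int, rotations: np.ndarray) -> np.ndarray:
    """Frequency-space sampling coordinates for central slices.

    Returns array of shape (n_rot, 3, B, B) holding (fz, fy, fx) index
    offsets (add the center to get array coordinates in a B^3 transform).
    """
    c = B // 2
    k = np.arange(B) - c
    kv, ku = np.meshgrid(k, k, indexing="ij")  # kv rows (vertical), ku cols
    plane = np.stack([ku, np.zeros_like(ku), kv], axis=0).reshape(3, -1).astype(np.float64)
    # f_vol = R^T k_lab
    f = np.einsum("rji,jk->rik", rotations, plane)  # (n_rot, 3:xyz, B*B)
    # reorder to (z, y, x) index offsets
    f = f[:, ::-1, :]
    return f.reshape(len(rotations), 3, B, B)


def extract_slices(volF: np.ndarray, rotations: np.ndarray, order: int = 1) -> np.ndarray:
    """Extract central slices from a centered 3D transform.

    Parameters
    ----------
    volF : complex (N, N, N) centered Fourier transform.
    rotations : (n_rot, 3, 3) volume-to-lab matrices.

    Returns complex64 array (n_rot, N, N) of projection transforms
    F2[kv, ku].
    """
    B = volF.shape[0]
    c = B // 2
    f = _slice_freqs(B, np.asarray(rotations, dtype=np.float64))
    coords = (f + c).reshape(len(rotations) * 3, B * B)
    coords = coords.reshape(len(rotations), 3, -1)
    out = np.empty((len(rotations), B * B), dtype=np.complex64)
    re = np.ascontiguousarray(volF.real, dtype=np.float32)
    im = np.ascontiguousarray(volF.imag, dtype=np.float32)
    for i in range(len(rotations)):
        rr = map_coordinates(re, coords[i], order=order, mode="constant", cval=0.0)
        ii = map_coordinates(im, coords[i], order=order, mode="constant", cval=0.0)
        out[i] = rr + 1j * ii
    return out.reshape(len(rotations), B, B)


def insert_slices(
    slices: np.ndarray,
    rotations: np.ndarray,
    N: int,
    accum: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid central slices into a 3D Fourier accumulator (direct Fourier
    inversion with trilinear gridding).

    Returns ``(accum, weights)``; pass them back in to accumulate further
    slices.  Normalize with :func:`finish_insert`.
    """
    B = slices.shape[-1]
    c = N // 2
    size = N * N * N
    if accum is None:
        accum = np.zeros((N, N, N), dtype=np.complex128)
    if weights is None:
        weights = np.zeros((N, N, N), dtype=np.float64)
    f = _slice_freqs(B, np.asarray(rotations, dtype=np.float64)) + c  # (n,3,B,B)
    vals = slices.reshape(len(slices), -1)
    coords = f.reshape(len(slices), 3, -1)
    acc_flat = accum.reshape(-1)
    w_flat = weights.reshape(-1)
    z = coords[:, 0, :].reshape(-1)
    y = coords[:, 1, :].reshape(-1)
    x = coords[:, 2, :].reshape(-1)
    v = vals.reshape(-1).astype(np.complex128)
    bz = np.floor(z).astype(np.int64)
    by = np.floor(y).astype(np.int64)
    bx = np.floor(x).astype(np.int64)
    fz, fy, fx = z - bz, y - by, x - bx
    ok = (bz >= 0) & (bz < N - 1) & (by >= 0) & (by < N - 1) & (bx >= 0) & (bx < N - 1)
    bz, by, bx = bz[ok], by[ok], bx[ok]
    fz, fy, fx, v = fz[ok], fy[ok], fx[ok], v[ok]
    for dz in (0, 1):
        wz = fz if dz else 1.0 - fz
        for dy in (0, 1):
            wy = fy if dy else 1.0 - fy
            for dx in (0, 1):
                wx = fx if dx else 1.0 - fx
                w = wz * wy * wx
                idx = ((bz + dz) * N + (by + dy)) * N + (bx + dx)
                w_flat += np.bincount(idx, weights=w, minlength=size)
                acc_flat.real += np.bincount(idx, weights=w * v.real, minlength=size)
                acc_flat.imag += np.bincount(idx, weights=w * v.imag, minlength=size)
    return accum, weights


def finish_insert(accum: np.ndarray, weights: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Normalize an insertion accumulator and return the real-space volume."""
    F = accum / (weights + eps)
    vol = cifftn(F).real
    return vol.astype(np.float64)


def shift_phase(B: int, du: float, dv: float) -> np.ndarray:
    """Phase ramp that shifts an image by (du, dv) pixels when multiplied
    onto its centered transform F[kv, ku]."""
    c = B // 2
    k = np.arange(B) - c
    kv, ku = np.meshgrid(k, k, indexing="ij")
    return np.exp(-2j * np.pi * (ku * du + kv * dv) / B)
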