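"""Iterative helical real-space refinement (IHRSR).

The loop alternates four stages: (1) exhaustive projection matching of each
boxed segment against reference projections on an azimuth x out-of-plane
tilt grid, with in-plane angle, integer horizontal shift and sub-pixel
axial-phase search; (2) direct Fourier back-projection of the aligned
segments; (3) a search for the helical symmetry (twist, rise) that
maximizes the correlation between the reconstruction and its symmetrized
copy; (4) imposition of that symmetry by real-space averaging, giving the
next reference.  Starting from a featureless cylinder, the symmetry
parameters converge to the filament's true lattice.

Numerical notes: reference projections are central slices of the 3D
transform (projection-slice theorem); the symmetry search scores
candidates analytically in a cylindrical-harmonic representation, which is
exact for the resampled volume and makes a dense (twist, rise) scan cheap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage


from ._fourier import cfft2, cfftn, insert_slices, finish_insert, shift_phase, view_matrix
from .heligeom import HelicalSymmetry
from .synthgen import DensityVolume, SegmentStack
from ._fourier import extract_slices

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementState",
    "SortSpec",
    "AlignParams",
    "cylinder_reference",
    "align_to_reference",
    "backproject",
    "search_symmetry",
    "impose_symmetry",
    "run_ihrsr",
    "sort_by_symmetry",
]


@dataclass
class RefinementState:
    """Trace of one IHRSR refinement."""

    iteration: int
    symmetry: HelicalSymmetry
    reference: DensityVolume
    alignments: pd.DataFrame
    trace: pd.DataFrame
    converged: bool = False
    flags: list = field(default_factory=list)


@dataclass(frozen=True)
class SortSpec:
    """Symmetry-bin sorting grid: ``n_bins`` must be a perfect square; the
    grid is centered on ``center`` with steps ``d_twist`` x ``d_rise``."""

    center: HelicalSymmetry
    n_bins: int = 9
    d_twist: float = 2.0
    d_rise: float = 1.5

    def __post_init__(self):
        side = int(round(math.sqrt(self.n_bins)))
        if side * side != self.n_bins or self.n_bins < 1:
            raise ValueError("n_bins must be a perfect square >= 1")
        if self.d_twist <= 0 or self.d_rise <= 0:
            raise ValueError("bin steps must be positive")

    @property
    def side(self) -> int:
        return int(round(math.sqrt(self.n_bins)))

    def bin_symmetries(self) -> list[HelicalSymmetry]:
        half = (self.side - 1) // 2
        out = []
        sign = 1.0 if self.center.twist > 0 else -1.0
        for it in range(-half, self.side - half):
            for ir in range(-half, self.side - half):
                out.append(
                    HelicalSymmetry(
                        sign * (abs(self.center.twist) + it * self.d_twist),
                        self.center.rise + ir * self.d_rise,
                        self.center.n_start,
                    )
                )
        return out


@dataclass(frozen=True)
class AlignParams:
    """Projection-matching search grid."""

    azimuth_step: float = 4.0
    azimuth_max: float = 360.0
    tilt_range: float = 15.0
    tilt_step: float = 2.0
    inplane_range: float = 8.0
    inplane_step: float = 2.0
    max_shift_px: int = 8
    n_phase: int = 5  # axial-phase (y) samples over +-rise/2

    def tilt_grid(self) -> np.ndarray:
        if self.tilt_range <= 0 or self.tilt_step <= 0:
            return np.array([0.0])
        pos = np.arange(self.tilt_step, self.tilt_range + 1e-9, self.tilt_step)
        return np.concatenate([-pos[::-1], [0.0], pos])

    def inplane_grid(self) -> np.ndarray:
        if self.inplane_range <= 0 or self.inplane_step <= 0:
            return np.array([0.0])
        pos = np.arange(self.inplane_step, self.inplane_range + 1e-9, self.inplane_step)
        return np.concatenate([-pos[::-1], [0.0], pos])

    def azimuth_grid(self) -> np.ndarray:
        return np.arange(0.0, self.azimuth_max - 1e-9, self.azimuth_step)


def cylinder_reference(diameter: float, grid: int, voxel: float) -> DensityVolume:
    """Featureless solid cylinder along the helical axis with a one-voxel
    cosine edge falloff — the canonical unbiased IHRSR starting reference."""
    if diameter >= grid * voxel:
        raise ValueError("cylinder diameter exceeds the grid")
    c = grid // 2
    y, x = np.meshgrid(np.arange(grid) - c, np.arange(grid) - c, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2) * voxel
    R = diameter / 2.0
    w = voxel  # 1-voxel falloff
    disk = np.clip((R - r) / w + 0.5, 0.0, 1.0)
    disk = 0.5 - 0.5 * np.cos(np.pi * disk)
    vol = np.broadcast_to(disk, (grid, grid, grid)).copy()
    return DensityVolume(vol, voxel)


def _rotate_image(img: np.ndarray, deg: float) -> np.ndarray:
    """Rotate an image about its center; positive angle matches the
    ``inplane`` convention of the projection geometry."""
    if deg == 0.0:
        return np.asarray(img, dtype=np.float64)
    return ndimage.rotate(np.asarray(img, dtype=np.float64), deg, reshape=False, order=1)


def _reference_slices(reference: DensityVolume, params: AlignParams):
    """Central-slice transforms of the reference on the (azimuth, tilt)
    grid, plus the per-view orientation list."""
    VF = cfftn(reference.grid)
    azs = params.azimuth_grid()
    tilts = params.tilt_grid()
    views = [(a, t) for t in tilts for a in azs]
    Rs = np.array([view_matrix(a, t, 0.0) for a, t in views])
    P = extract_slices(VF, Rs)
    return np.array(views), P


class SegmentFFTCache:
    """In-plane-rotated segment transforms, computed once per stack and
    reused across refinement iterations."""

    def __init__(self, stack: SegmentStack, ip_grid: np.ndarray):
        B = stack.box
        c = B // 2
        self.ip_grid = np.asarray(ip_grid, dtype=float)
        nS, nG = len(stack), len(ip_grid)
        self.Sv = np.empty((nS * nG, B, B), dtype=np.complex64)
        for i, img in enumerate(stack.images):
            for g, gamma in enumerate(ip_grid):
                self.Sv[i * nG + g] = cfft2(_rotate_image(img, -gamma))
        self.Sv[:, c, c] = 0.0  # zero DC == mean subtraction
        self.norm = np.sqrt(np.sum(np.abs(self.Sv) ** 2, axis=(1, 2)))
        self.norm[self.norm == 0] = np.inf
        self.empty = ~np.any(stack.images, axis=(1, 2))


def align_to_reference(
    stack: SegmentStack,
    reference: DensityVolume,
    azimuth_step: float = 4.0,
    tilt_range: float = 15.0,
    tilt_step: float = 2.0,
    params: Optional[AlignParams] = None,
    rise_px: Optional[float] = None,
    chunk: int = 32,
    cache: Optional[SegmentFFTCache] = None,
) -> pd.DataFrame:
    """Exhaustive projection matching of every segment.

    Scores normalized cross-correlation over azimuth x tilt reference
    projections, in-plane angles in a window around vertical, integer
    horizontal shifts within ``max_shift_px`` and, when ``rise_px`` is
    given, ``n_phase`` sub-pixel axial shifts spanning one rise.  Returns a
    DataFrame (azimuth, tilt, inplane, xshift_px, yshift_px, corr, flagged).
    """
    if params is None:
        params = AlignParams(
            azimuth_step=azimuth_step, tilt_range=tilt_range, tilt_step=tilt_step
        )
    B = stack.box
    if reference.n != B:
        raise ValueError("reference grid and stack box size must match")
    views, P = _reference_slices(reference, params)
    nP = len(P)
    c = B // 2
    # axial-phase variants applied to the reference slices as phase ramps
    if rise_px is not None and params.n_phase > 1:
        ygrid = (np.arange(params.n_phase) / params.n_phase - 0.5 + 0.5 / params.n_phase) * rise_px
    else:
        ygrid = np.array([0.0])
    ramps = np.stack([shift_phase(B, 0.0, dy).astype(np.complex64) for dy in ygrid])
    Pv = (P[:, None, :, :] * ramps[None, :, :, :]).reshape(nP * len(ygrid), B, B)
    Pv[:, c, c] = 0.0
    normP = np.sqrt(np.sum(np.abs(Pv) ** 2, axis=(1, 2)))
    normP[normP == 0] = np.inf
    PvT = np.ascontiguousarray(np.conj(Pv).transpose(2, 1, 0))  # (kx, kv, p)

    ip_grid = params.inplane_grid()
    if cache is None or not np.array_equal(cache.ip_grid, ip_grid):
        cache = SegmentFFTCache(stack, ip_grid)
    nG = len(ip_grid)
    dx_window = np.arange(-params.max_shift_px, params.max_shift_px + 1)
    # phase matrix turning C(kx) into correlation at the windowed shifts
    kx = (np.arange(B) - c)
    E = np.exp(2j * np.pi * np.outer(kx, dx_window) / B).astype(np.complex64)

    out = []
    nPv = Pv.shape[0]
    for s0 in range(0, len(stack), chunk):
        s1 = min(s0 + chunk, len(stack))
        Sv = cache.Sv[s0 * nG:s1 * nG]
        normS = cache.norm[s0 * nG:s1 * nG]
        nSv = Sv.shape[0]
        # C[s, p, kx] = sum_kv S * conj(P), batched GEMM over kx
        A = np.ascontiguousarray(Sv.transpose(2, 0, 1))  # (kx, s, kv)
        M = np.matmul(A, PvT).transpose(1, 2, 0)          # (s, p, kx)
        Cdx = (M.reshape(nSv * nPv, B) @ E).real.reshape(nSv, nPv, len(dx_window))
        Cdx /= normS[:, None, None]
        Cdx /= normP[None, :, None]
        flat = Cdx.reshape(s1 - s0, nG, nP, len(ygrid), len(dx_window))
        for i in range(s1 - s0):
            gi, pi, yi, di = np.unravel_index(np.argmax(flat[i]), flat[i].shape)
            corr = float(flat[i, gi, pi, yi, di])
            az, ti = views[pi]
            flagged = bool(di == 0 or di == len(dx_window) - 1)
            if cache.empty[s0 + i]:
                corr, flagged = 0.0, True
            out.append(
                dict(azimuth=float(az), tilt=float(ti), inplane=float(ip_grid[gi]),
                     xshift_px=int(dx_window[di]), yshift_px=float(ygrid[yi]),
                     corr=corr, flagged=flagged)
            )
    return pd.DataFrame(out)


def backproject(
    stack: SegmentStack,
    alignments: pd.DataFrame,
    grid: Optional[int] = None,
) -> DensityVolume:
    """Direct Fourier reconstruction from aligned segments.

    Each segment (in-plane rotated back to vertical, shifts removed as
    phase ramps) is inserted as a central slice at its assigned
    orientation; trilinear gridding weights normalize the anisotropic
    azimuth coverage.
    """
    if len(alignments) != len(stack):
        raise ValueError("alignments must cover the whole stack")
    if len(stack) < 10:
        logger.warning("back-projecting %d segments: volume will be unreliable", len(stack))
    B = stack.box
    N = grid or B
    if N != B:
        raise ValueError("grid must equal the box size for slice insertion")
    slices = np.empty((len(stack), B, B), dtype=np.complex64)
    Rs = np.empty((len(stack), 3, 3))
    for i, (img, row) in enumerate(zip(stack.images, alignments.itertuples())):
        F = cfft2(_rotate_image(img, -row.inplane))
        F = F * shift_phase(B, -row.xshift_px, -row.yshift_px)
        slices[i] = F
        Rs[i] = view_matrix(row.azimuth, row.tilt, 0.0)
    acc, w = insert_slices(slices, Rs, N)
    vol = finish_insert(acc, w)
    return DensityVolume(vol / max(len(stack), 1), stack.pixel)


# ---------------------------------------------------------------------------
# symmetry search / imposition

class _CylSpectrum:
    """Cylindrical-harmonic cross-spectrum of a volume against its centrally
    windowed copy; lets the symmetrized-copy correlation be evaluated
    analytically for any candidate (twist, rise)."""

    def __init__(self, volume: DensityVolume, r_max: Optional[float] = None,
                 n_phi: int = 360, window_frac: float = 0.5):
        g = volume.grid
        N = g.shape[0]
        c = N // 2
        self.voxel = volume.voxel
        self.N = N
        if r_max is None:
            r_max = (c - 2) * volume.voxel
        radii = np.arange(1.0, r_max / volume.voxel)  # voxel units
        phis = np.arange(n_phi) * (2 * np.pi / n_phi)
        rr, pp = np.meshgrid(radii, phis, indexing="ij")
        xs = rr * np.cos(pp) + c
        ys = rr * np.sin(pp) + c
        zs = np.arange(N)
        coords = np.stack(
            [
                np.broadcast_to(zs[:, None, None], (N,) + rr.shape).ravel(),
                np.broadcast_to(ys[None], (N,) + rr.shape).ravel(),
                np.broadcast_to(xs[None], (N,) + rr.shape).ravel(),
            ]
        )
        cyl = ndimage.map_coordinates(g, coords, order=1, mode="constant").reshape(
            (N, len(radii), n_phi)
        )
        # central z window with cosine taper; margin limits usable shift
        self.margin = int(math.floor((1.0 - window_frac) * N / 2.0))
        win = np.zeros(N)
        lo, hi = self.margin, N - self.margin
        win[lo:hi] = 1.0
        taper = max(2, self.margin // 2)
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(taper) / taper)
        win[lo:lo + taper] *= ramp
        win[hi - taper:hi] *= ramp[::-1]
        A = cyl * win[:, None, None]
        FA = np.fft.fft(np.fft.fft(A, axis=0), axis=2)
        FB = np.fft.fft(np.fft.fft(cyl, axis=0), axis=2)
        w_r = np.arange(1.0, r_max / volume.voxel)  # area weight ~ r
        self.Q = np.einsum("zrm,r,zrm->zm", np.conj(FA), w_r, FB)
        self.normA = float(np.einsum("zrm,r->", np.abs(FA) ** 2, w_r).real)
        self.normB = float(np.einsum("zrm,r->", np.abs(FB) ** 2, w_r).real)
        self.n_phi = n_phi
        self.kz = np.fft.fftfreq(N)  # cycles per voxel
        self.m = np.fft.fftfreq(n_phi) * n_phi  # harmonic numbers

    def _q_cn(self, n_start: int):
        """Q restricted to angular harmonics that survive C_n averaging
        (m = 0 mod n), plus the full-Q total for the pure-rotation terms."""
        if getattr(self, "_qcn_n", None) != n_start:
            msel = np.nonzero(np.mod(np.abs(self.m), n_start) == 0)[0]
            self._qcn_n = n_start
            self._qcn = self.Q[:, msel]
            self._qcn_m = self.m[msel]
            self._q_total = float(np.sum(self.Q).real)
            self._qcn_total = float(np.sum(self._qcn).real)
        return self._qcn, self._qcn_m

    def score(self, twist: float, rise: float, n_start: int) -> float:
        """Normalized correlation between the windowed volume and the
        average of its helically + C(n_start) transformed copies.

        Averaging over the C_n rotations cancels all angular harmonics
        except multiples of n, so the (twist, rise) terms reduce to a
        phase-weighted sum over the reduced cross-spectrum.
        """
        rise_vox = rise / self.voxel
        K = max(1, int(math.floor(self.margin / max(rise_vox, 1e-9))))
        ks = [k for k in range(-K, K + 1) if k != 0]
        if not ks:
            return -1.0
        Qc, mc = self._q_cn(n_start)
        total = 0.0
        count = 0
        for k in ks:
            a = math.radians(k * twist)
            u = np.exp(2j * np.pi * self.kz * (k * rise_vox))
            v = np.exp(1j * mc * a)
            total += n_start * float((u @ Qc @ v).real)
            count += n_start
        # pure C_n rotations (k = 0, j > 0)
        total += n_start * self._qcn_total - self._q_total
        count += n_start - 1
        return total / count / math.sqrt(self.normA * self.normB)


def search_symmetry(
    volume: DensityVolume,
    init: HelicalSymmetry,
    bounds: tuple[float, float] = (3.0, 2.0),
    step_schedule: Sequence[tuple[float, float]] = ((0.5, 0.5), (0.1, 0.1), (0.02, 0.02)),
    r_max: Optional[float] = None,
) -> tuple[HelicalSymmetry, float, bool]:
    """Grid search with step refinement for the (twist, rise) maximizing
    the volume-vs-symmetrized-copy correlation; ``n_start`` is fixed.

    ``bounds`` are half-widths around ``init`` (degrees, Angstrom).
    Returns (symmetry, score, edge_flag); an optimum pinned to a bounds
    edge is flagged, not silently accepted.
    """
    spec = _CylSpectrum(volume, r_max=r_max)
    sign = 1.0 if init.twist > 0 else -1.0
    t0, r0 = abs(init.twist), init.rise
    t_lo, t_hi = t0 - bounds[0], t0 + bounds[0]
    r_lo, r_hi = max(r0 - bounds[1], volume.voxel * 0.51), r0 + bounds[1]
    best_t, best_r = t0, r0
    edge = False
    for si, (dt, dr) in enumerate(step_schedule):
        if si == 0:
            ts = np.arange(t_lo, t_hi + 1e-9, dt)
            rs = np.arange(r_lo, r_hi + 1e-9, dr)
        else:
            prev_dt, prev_dr = step_schedule[si - 1]
            ts = np.clip(np.arange(best_t - prev_dt, best_t + prev_dt + 1e-9, dt), t_lo, t_hi)
            rs = np.clip(np.arange(best_r - prev_dr, best_r + prev_dr + 1e-9, dr), r_lo, r_hi)
        scores = np.array([[spec.score(sign * t, r, init.n_start) for r in rs] for t in ts])
        it, ir = np.unravel_index(np.argmax(scores), scores.shape)
        best_t, best_r = float(ts[it]), float(rs[ir])
        if si == 0 and (it in (0, len(ts) - 1) or ir in (0, len(rs) - 1)):
            edge = True
    best = float(spec.score(sign * best_t, best_r, init.n_start))
    if edge:
        logger.warning("symmetry search optimum at bounds edge: twist %.2f rise %.2f", best_t, best_r)
    return HelicalSymmetry(sign * best_t, best_r, init.n_start), best, edge


def _helical_op(grid: np.ndarray, angle_deg: float, dz_vox: float) -> np.ndarray:
    """Apply rotation about z by ``angle_deg`` plus axial shift ``dz_vox``
    (voxels) to a volume (z, y, x), linear interpolation."""
    N = grid.shape[0]
    c = N // 2
    a = math.radians(angle_deg)
    ca, sa = math.cos(a), math.sin(a)
    # out(p) = in(M @ (p - center) + center - (dz, 0, 0))
    M = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    center = np.array([c, c, c])
    offset = center - M @ center
    offset[0] -= dz_vox
    return ndimage.affine_transform(grid, M, offset=offset, order=1, mode="constant", cval=0.0)


def impose_symmetry(
    volume: DensityVolume,
    sym: HelicalSymmetry,
    overlap_frac: float = 0.6,
) -> DensityVolume:
    """Average the volume over its helical + C(n_start) symmetry mates.

    Includes every helical operation whose axially translated copy still
    overlaps at least ``overlap_frac`` of the volume height; per-z-plane
    weights keep the average unbiased near the ends.
    """
    if sym.rise < volume.voxel:
        raise ValueError("rise below one voxel: symmetry undersampled")
    g = volume.grid.astype(np.float32)
    N = g.shape[0]
    dz_vox = sym.rise / volume.voxel
    K = int(math.floor((1.0 - overlap_frac) * N / dz_vox))
    acc = np.zeros_like(g)
    wts = np.zeros(N)
    z_idx = np.arange(N)
    for k in range(-K, K + 1):
        for j in range(sym.n_start):
            ang = k * sym.twist + j * 360.0 / sym.n_start
            dz = k * dz_vox
            if k == 0 and j == 0:
                acc += g
            else:
                acc += _helical_op(g, ang, dz)
            wts += ((z_idx - dz >= 0) & (z_idx - dz <= N - 1)).astype(float)
    acc = acc / np.maximum(wts, 1e-6)[:, None, None].astype(np.float32)
    return DensityVolume(acc.astype(np.float64), volume.voxel)


# ---------------------------------------------------------------------------
# the loop

def run_ihrsr(
    stack: SegmentStack,
    init_sym: HelicalSymmetry,
    max_iters: int = 150,
    tol_twist: float = 0.05,
    tol_rise: float = 0.05,
    perturb: Optional[tuple[int, float]] = None,
    align_params: Optional[AlignParams] = None,
    cylinder_diameter: float = 90.0,
    search_bounds: tuple[float, float] = (3.0, 2.0),
    reference: Optional[DensityVolume] = None,
    search_from_iter: int = 1,
    callback=None,
) -> RefinementState:
    """Full IHRSR refinement from a featureless cylinder.

    Convergence is declared when twist and rise each changed by less than
    the tolerances over 5 consecutive iterations.  ``perturb=(it, d_rise)``
    adds ``d_rise`` Angstrom to the rise estimate at iteration ``it`` and
    lets the loop recover (robustness protocol).
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    B = stack.box
    if align_params is None:
        align_params = AlignParams(azimuth_max=360.0 / init_sym.n_start)
    if reference is None:
        reference = cylinder_reference(cylinder_diameter, B, stack.pixel)
    sym = init_sym
    trace = []
    alignments = None
    converged = False
    flags = []
    cache = SegmentFFTCache(stack, align_params.inplane_grid())
    for it in range(max_iters):
        rise_px = sym.rise / stack.pixel
        alignments = align_to_reference(
            stack, reference, params=align_params, rise_px=rise_px, cache=cache
        )
        raw = backproject(stack, alignments)
        if it < search_from_iter:
            # the first reconstruction, aligned against a featureless
            # cylinder, carries no reliable lattice yet: keep the initial
            # symmetry and let structure emerge before searching
            sym_new, score, edge = sym, float("nan"), False
        else:
            sym_new, score, edge = search_symmetry(raw, sym, bounds=search_bounds)
        if edge:
            flags.append(f"iter {it}: symmetry optimum at search bounds edge")
        if perturb is not None and it == perturb[0]:
            sym_new = HelicalSymmetry(sym_new.twist, sym_new.rise + perturb[1], sym_new.n_start)
            flags.append(f"iter {it}: rise perturbed by {perturb[1]:+.2f} A")
        sym = sym_new
        reference = impose_symmetry(raw, sym)
        mean_corr = float(alignments["corr"].mean())
        trace.append(dict(iteration=it, twist=sym.twist, rise=sym.rise,
                          mean_corr=mean_corr, sym_score=score))
        if callback is not None:
            callback(it, sym, mean_corr)
        logger.info("iter %d: twist %.3f rise %.3f corr %.4f", it, sym.twist, sym.rise, mean_corr)
        if len(trace) >= 6:
            recent = trace[-6:]
            dt = max(abs(recent[i + 1]["twist"] - recent[i]["twist"]) for i in range(5))
            dr = max(abs(recent[i + 1]["rise"] - recent[i]["rise"]) for i in range(5))
            pert_recent = perturb is not None and perturb[0] > it - 6
            if dt < tol_twist and dr < tol_rise and not pert_recent:
                converged = True
                break
    if not converged:
        flags.append("not converged at max_iters")
    return RefinementState(
        iteration=len(trace) - 1,
        symmetry=sym,
        reference=reference,
        alignments=alignments,
        trace=pd.DataFrame(trace),
        converged=converged,
        flags=flags,
    )


def sort_by_symmetry(
    stack: SegmentStack,
    spec: SortSpec,
    volume: DensityVolume,
    align_params: Optional[AlignParams] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sort segments into symmetry bins.

    Builds one reference per bin by imposing that bin's (twist, rise) on
    the given (unsymmetrized) reconstruction, aligns every segment against
    each, and assigns it to the best-correlating bin.  Returns
    (assignment per segment, counts per bin in grid order).
    """
    syms = spec.bin_symmetries()
    if align_params is None:
        align_params = AlignParams(azimuth_max=360.0 / spec.center.n_start)
    corrs = np.empty((len(stack), len(syms)))
    cache = SegmentFFTCache(stack, align_params.inplane_grid())
    for b, s in enumerate(syms):
        ref = impose_symmetry(volume, s)
        al = align_to_reference(
            stack, ref, params=align_params, rise_px=s.rise / stack.pixel, cache=cache
        )
        corrs[:, b] = al["corr"].to_numpy()
    assign = np.argmax(corrs, axis=1)
    counts = np.bincount(assign, minlength=len(syms))
    return assign, counts
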