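"""Synthetic filament data: helically symmetric volumes and noisy boxed
projection segments with known ground truth.

The subunit is modeled as a set of Gaussian blobs anchored at the strand
radius; a filament is the blob set replicated over the helical lattice
(:func:`helixforge.heligeom.place_subunits`).  Segments are rendered
analytically — the projection of a 3D Gaussian along any direction is a 2D
Gaussian of the same sigma — so generation is exact and independent of the
volume-interpolation projector used during reconstruction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import heligeom
from ._fourier import view_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubunitTemplate",
    "DensityVolume",
    "CTFParams",
    "SegmentStack",
    "card_template",
    "decorated_template",
    "build_volume",
    "project",
    "render_segment",
    "simulate_segments",
    "noise_sigma_for_snr",
    "ctf_eval",
    "ctf_filter",
    "rescale_stack",
]


@dataclass(frozen=True)
class SubunitTemplate:
    """Gaussian-blob pseudo-subunit.

    ``blobs`` is a sequence of ``(offset, amplitude, width)`` where offset
    is a 3-vector in Angstrom relative to the subunit anchor point (the
    anchor sits at the strand radius, azimuth 0), amplitude is arbitrary
    density units and width the Gaussian sigma in Angstrom.
    """

    blobs: tuple

    def __post_init__(self):
        blobs = tuple(
            (np.asarray(o, dtype=float), float(a), float(w)) for o, a, w in self.blobs
        )
        for o, a, w in blobs:
            if o.shape != (3,):
                raise ValueError("blob offset must be a 3-vector")
            if w <= 0:
                raise ValueError("blob width must be positive")
        object.__setattr__(self, "blobs", blobs)

    @property
    def max_extent(self) -> float:
        """Largest |offset| + 4 sigma, Angstrom."""
        return max(np.linalg.norm(o) + 4 * w for o, _, w in self.blobs)


@dataclass
class DensityVolume:
    """Cubic voxel grid, helical axis along z (numpy axis 0, MRC sections)."""

    grid: np.ndarray
    voxel: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("grid must be a cubic N x N x N array")
        if self.grid.shape[0] < 16:
            raise ValueError("grid must be at least 16^3")
        if not (self.voxel > 0):
            raise ValueError("voxel size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel)


@dataclass(frozen=True)
class CTFParams:
    """Contrast-transfer parameters (underfocus positive, microns)."""

    defocus_um: float
    voltage_kv: float = 300.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.07

    def __post_init__(self):
        if self.defocus_um < 0:
            raise ValueError("defocus must be >= 0 (underfocus positive)")
        if not (0.0 <= self.amplitude_contrast <= 1.0):
            raise ValueError("amplitude contrast must be in [0, 1]")


@dataclass
class SegmentStack:
    """Boxed filament segments plus per-segment ground truth / alignments.

    ``records`` has one row per image with at least: filament, segment,
    offset_px (axial boxing offset), azimuth, tilt, inplane (degrees),
    xshift_px, zphase (Angstrom, axial offset of the lattice relative to
    the box center, in [0, rise)).
    """

    images: np.ndarray
    pixel: float
    records: pd.DataFrame
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be (M, B, B)")
        if len(self.records) != len(self.images):
            raise ValueError("records and images length mismatch")

    @property
    def box(self) -> int:
        return self.images.shape[1]

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "SegmentStack":
        idx = np.asarray(idx)
        return SegmentStack(
            self.images[idx], self.pixel,
            self.records.iloc[idx].reset_index(drop=True),
            self.seed, dict(self.meta),
        )


# ---------------------------------------------------------------------------
# default templates

def card_template() -> SubunitTemplate:
    """Default chiral pseudo-subunit: three short Gaussian rods mimicking
    the rod-like peripheral helices of a small alpha-helical domain.

    Rod directions and offsets are deliberately non-coplanar with the
    helical axis so the generated filament is chiral and handedness tests
    are meaningful.
    """
    def rod(center, direction, half, amp, width, nb=3):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        c = np.asarray(center, float)
        return [(c + t * half * d, amp, width) for t in np.linspace(-1, 1, nb)]

    blobs = []
    blobs += rod((0.0, 0.0, 0.0), (0.3, 0.55, 0.78), 7.0, 1.0, 3.5)
    blobs += rod((6.0, -5.0, 4.0), (-0.6, 0.4, 0.7), 6.0, 0.9, 3.0)
    blobs += rod((-5.0, 6.0, -5.0), (0.8, -0.2, 0.55), 6.0, 0.9, 3.0)
    return SubunitTemplate(tuple(blobs))


def decorated_template(shell_offset: float = 15.0) -> SubunitTemplate:
    """Core template plus fragmented peripheral blobs ``shell_offset``
    Angstrom radially outside the core, emulating a filament whose core
    carries a loosely attached outer sheet of density."""
    core = list(card_template().blobs)
    periph = [
        ((shell_offset, 3.0, 6.0), 0.45, 3.0),
        ((shell_offset + 1.5, -4.0, -3.0), 0.40, 3.2),
        ((shell_offset - 1.0, 6.5, -7.0), 0.35, 2.8),
    ]
    return SubunitTemplate(tuple(core + periph))


# ---------------------------------------------------------------------------
# blob placement and rendering

def _filament_blobs(
    sym: heligeom.HelicalSymmetry,
    template: SubunitTemplate,
    radius: float,
    z_min: float,
    z_max: float,
    z_shift: float = 0.0,
):
    """All blob (position, amplitude, width) for lattice layers whose
    anchors fall in [z_min, z_max] (Angstrom); the whole lattice is shifted
    axially by ``z_shift``."""
    k_lo = math.floor((z_min - z_shift) / sym.rise)
    k_hi = math.ceil((z_max - z_shift) / sym.rise)
    anchor = np.array([radius, 0.0, 0.0])
    positions, amps, widths = [], [], []
    for k in range(k_lo, k_hi + 1):
        z = k * sym.rise + z_shift
        for j in range(sym.n_start):
            az = k * sym.twist + j * 360.0 / sym.n_start
            c, s = math.cos(math.radians(az)), math.sin(math.radians(az))
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            for off, a, w in template.blobs:
                p = R @ (anchor + off)
                positions.append([p[0], p[1], p[2] + z])
                amps.append(a)
                widths.append(w)
    return np.array(positions), np.array(amps), np.array(widths)


def build_volume(
    sym: heligeom.HelicalSymmetry,
    template: SubunitTemplate,
    radius: float,
    grid: int = 96,
    voxel: float = 2.26,
) -> DensityVolume:
    """Render the helically symmetric blob lattice into a cubic volume.

    The lattice spans the grid height plus a 4-sigma margin so the volume
    is invariant under the generating (twist, rise) operation away from
    the axial edges.
    """
    half = grid * voxel / 2.0
    if radius + template.max_extent > half:
        raise ValueError(
            f"template at radius {radius} A exceeds grid half-width {half} A"
        )
    margin = template.max_extent
    pos, amps, widths = _filament_blobs(sym, template, radius, -half - margin, half + margin)
    vol = np.zeros((grid, grid, grid))
    c = grid // 2
    # evaluate each blob on a local 4-sigma window
    for p, a, w in zip(pos, amps, widths):
        r_vox = 4.0 * w / voxel
        ctr = p[::-1] / voxel + c  # (z, y, x) voxel coords
        lo = np.maximum(np.floor(ctr - r_vox).astype(int), 0)
        hi = np.minimum(np.ceil(ctr + r_vox).astype(int) + 1, grid)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            *(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij"
        )
        d2 = ((zz - ctr[0]) ** 2 + (yy - ctr[1]) ** 2 + (xx - ctr[2]) ** 2) * voxel ** 2
        vol[zz, yy, xx] += a * np.exp(-d2 / (2.0 * w ** 2))
    return DensityVolume(vol, voxel)


def project(
    volume: DensityVolume,
    azimuth: float = 0.0,
    tilt: float = 0.0,
    inplane: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Line-integral projection of a volume.

    The volume is rotated by ``Ry(inplane) Rx(tilt) Rz(azimuth)`` and
    integrated along lab y; at zero tilt and in-plane angle the helical
    axis maps to the image vertical.  ``shift`` translates the image by
    (du, dv) pixels.  Output in density * Angstrom units.
    """
    if abs(tilt) > 60:
        raise ValueError("|tilt| must be <= 60 degrees")
    N = volume.n
    c = N // 2
    R = view_matrix(azimuth, tilt, inplane)
    u = np.arange(N) - c
    v = np.arange(N) - c
    w = np.arange(N) - c
    vv, uu = np.meshgrid(v, u, indexing="ij")
    du, dv = shift
    img = np.zeros((N, N))
    # sample volume at R^T (u - du, w, v - dv), accumulate over depth w
    base = np.stack([uu - du, np.zeros_like(uu, dtype=float), vv - dv], axis=0)
    for wk in w:
        pts = base.copy()
        pts[1] = wk
        q = np.tensordot(R.T, pts, axes=(1, 0))  # (3:xyz, N, N)
        coords = np.stack([q[2] + c, q[1] + c, q[0] + c], axis=0)
        img += ndimage.map_coordinates(volume.grid, coords, order=1, mode="constant")
    return img * volume.voxel


def render_segment(
    sym: heligeom.HelicalSymmetry,
    template: SubunitTemplate,
    radius: float,
    box: int,
    pixel: float,
    azimuth: float,
    tilt: float = 0.0,
    inplane: float = 0.0,
    xshift_px: float = 0.0,
    zphase: float = 0.0,
) -> np.ndarray:
    """Analytic clean projection of one boxed filament segment.

    ``zphase`` shifts the helical lattice axially (Angstrom) relative to
    the box center; the projected Gaussian of each blob is evaluated in
    closed form (amplitude * width * sqrt(2 pi) at the projected center).
    """
    half = box * pixel / 2.0
    margin = template.max_extent + abs(math.sin(math.radians(tilt))) * half + 10.0
    pos, amps, widths = _filament_blobs(
        sym, template, radius, -half - margin, half + margin, z_shift=zphase
    )
    R = view_matrix(azimuth, tilt, inplane)
    p = pos @ R.T  # lab coords
    cu = p[:, 0] / pixel + xshift_px  # horizontal, px relative to center
    cv = p[:, 2] / pixel             # vertical
    c = box // 2
    img = np.zeros((box, box))
    wpx = widths / pixel
    win = int(math.ceil(4 * wpx.max())) + 1
    iu0 = np.round(cu).astype(int) + c
    iv0 = np.round(cv).astype(int) + c
    keep = (iu0 > -win) & (iu0 < box + win) & (iv0 > -win) & (iv0 < box + win)
    d = np.arange(-win, win + 1)
    dV, dU = np.meshgrid(d, d, indexing="ij")
    for p_idx in np.nonzero(keep)[0]:
        uu = iu0[p_idx] + dU
        vv = iv0[p_idx] + dV
        du = (uu - c) - cu[p_idx]
        dv = (vv - c) - cv[p_idx]
        g = (
            amps[p_idx]
            * widths[p_idx]
            * math.sqrt(2 * math.pi)
            * np.exp(-(du ** 2 + dv ** 2) / (2 * wpx[p_idx] ** 2))
        )
        ok = (uu >= 0) & (uu < box) & (vv >= 0) & (vv < box)
        np.add.at(img, (vv[ok], uu[ok]), g[ok])
    return img


def noise_sigma_for_snr(clean_images: np.ndarray, snr: float) -> float:
    """Noise sigma so that signal variance / noise variance = snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    sig_var = float(np.mean([img.var() for img in clean_images]))
    return math.sqrt(sig_var / snr)


def simulate_segments(
    sym: heligeom.HelicalSymmetry,
    template: SubunitTemplate,
    n_filaments: int,
    length: int,
    box: int = 200,
    overlap: float = 0.9,
    noise_sigma: float = 0.0,
    ctf: Optional[CTFParams] = None,
    seed: int = 0,
    pixel: float = 2.26,
    radius: float = 32.0,
    tilt_jitter: float = 10.0,
    inplane_jitter: float = 5.0,
    shift_jitter_px: float = 3.0,
    snr: Optional[float] = None,
) -> SegmentStack:
    """Simulate boxed segments of noisy filament images.

    Per filament of ``length`` pixels, segments of ``box`` pixels are cut
    at stride ``box * (1 - overlap)``; filaments shorter than the box are
    discarded (and counted in ``meta['discarded']``).  Each segment views
    the filament at a uniform random azimuth, a uniform out-of-plane tilt
    within ``tilt_jitter``, an in-plane angle within ``inplane_jitter``
    and a sub-pixel horizontal shift within ``shift_jitter_px``; white
    Gaussian noise of ``noise_sigma`` (or sigma derived from ``snr``,
    signal variance / noise variance) and an optional CTF are then
    applied.  As in real boxing from micrographs, overlapping segments
    of one filament share the noise of their common pixels: noise is
    drawn once per filament as a tall canvas and windowed per segment.
    Fully determined by ``seed``.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    rng = np.random.default_rng(seed)
    stride = box * (1.0 - overlap)
    if stride < 1:
        raise ValueError("overlap too high: stride below one pixel")
    lengths = (
        [int(length)] * n_filaments
        if np.isscalar(length)
        else [int(v) for v in length]
    )
    if len(lengths) != n_filaments:
        raise ValueError("length sequence must have n_filaments entries")
    images, rows = [], []
    discarded = 0
    for f, flen in enumerate(lengths):
        zphase0 = rng.uniform(0.0, sym.rise)
        if flen < box:
            discarded += 1
            continue
        n_seg = int(math.floor((flen - box) / stride)) + 1
        for i in range(n_seg):
            offset = i * stride
            azimuth = rng.uniform(0.0, 360.0)
            tilt = rng.uniform(-tilt_jitter, tilt_jitter)
            inplane = rng.uniform(-inplane_jitter, inplane_jitter)
            xshift = rng.uniform(-shift_jitter_px, shift_jitter_px)
            # lattice axial phase relative to this segment's box center
            zc = (offset + box / 2.0) * pixel
            zphase = (zphase0 - zc) % sym.rise
            img = render_segment(
                sym, template, radius, box, pixel,
                azimuth, tilt, inplane, xshift, zphase,
            )
            images.append(img)
            rows.append(
                dict(filament=f, segment=i, offset_px=offset, azimuth=azimuth,
                     tilt=tilt, inplane=inplane, xshift_px=xshift, zphase=zphase)
            )
    if discarded:
        logger.info("discarded %d filaments shorter than the box", discarded)
    if not images:
        raise ValueError("no segments generated (all filaments shorter than box?)")
    images = np.asarray(images, dtype=np.float32)
    if snr is not None:
        noise_sigma = noise_sigma_for_snr(images, snr)
    if ctf is not None:
        images = np.stack([ctf_filter(im, ctf, "apply", pixel=pixel) for im in images])
    if noise_sigma > 0:
        # per-filament noise canvas: overlapping segments of one filament
        # share the noise of their common rows, as in real boxing
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
        images = images.astype(np.float64)
        i = 0
        for f, flen in enumerate(lengths):
            if flen < box:
                continue
            canvas = noise_rng.normal(0.0, noise_sigma, (flen, box))
            n_seg = int(math.floor((flen - box) / stride)) + 1
            for s in range(n_seg):
                off = int(round(s * stride))
                images[i] += canvas[off:off + box, :]
                i += 1
        assert i == len(images)
    stack = SegmentStack(
        images.astype(np.float32), pixel,
        pd.DataFrame(rows), seed,
        meta=dict(discarded=discarded, noise_sigma=float(noise_sigma),
                  radius=radius, twist=sym.twist, rise=sym.rise,
                  n_start=sym.n_start, ctf=ctf),
    )
    return stack


# ---------------------------------------------------------------------------
# CTF

def ctf_eval(ctf: CTFParams, s: np.ndarray) -> np.ndarray:
    """CTF value at spatial frequency ``s`` (1/Angstrom).

    chi(s) = pi lambda z s^2 - (pi/2) Cs lambda^3 s^4;
    CTF = -(sqrt(1 - A^2) sin chi + A cos chi), underfocus positive.
    """
    v = ctf.voltage_kv * 1e3
    lam = 12.2639 / math.sqrt(v * (1.0 + v * 0.97845e-6))  # Angstrom
    z = ctf.defocus_um * 1e4  # Angstrom
    cs = ctf.cs_mm * 1e7
    chi = math.pi * lam * z * s ** 2 - 0.5 * math.pi * cs * lam ** 3 * s ** 4
    a = ctf.amplitude_contrast
    return -(math.sqrt(1.0 - a ** 2) * np.sin(chi) + a * np.cos(chi))


def ctf_filter(
    image: np.ndarray,
    ctf: CTFParams,
    mode: str = "apply",
    pixel: float = 2.26,
    wiener_c: float = 0.2,
) -> np.ndarray:
    """Apply / phase-flip / Wiener-filter an image with the given CTF.

    ``apply`` multiplies the transform by the CTF; ``phase_flip`` by
    sign(CTF); ``wiener`` by CTF / (CTF^2 + c), the linear restoration
    filter for 1/SNR = c.
    """
    B = image.shape[0]
    k = np.fft.fftfreq(B, d=pixel)
    kv, ku = np.meshgrid(k, k, indexing="ij")
    s = np.sqrt(ku ** 2 + kv ** 2)
    C = ctf_eval(ctf, s)
    F = np.fft.fft2(image)
    if mode == "apply":
        F = F * C
    elif mode == "phase_flip":
        F = F * np.sign(C)
    elif mode == "wiener":
        if wiener_c <= 0:
            raise ValueError("wiener constant must be positive")
        F = F * C / (C ** 2 + wiener_c)
    else:
        raise ValueError(f"unknown ctf_filter mode {mode!r}")
    return np.fft.ifft2(F).real


def rescale_stack(stack: SegmentStack, new_pixel: float) -> SegmentStack:
    """Resample a stack to a new pixel size, preserving physical scale.

    The box is re-cropped / padded to a common even size.  Upsampling by
    more than 4x triggers a warning (no information is created).
    """
    if new_pixel <= 0:
        raise ValueError("new_pixel must be positive")
    factor = stack.pixel / new_pixel
    if factor > 4.0:
        logger.warning("upsampling by %.2fx creates no information", factor)
    B = stack.box
    newB = int(round(B * factor / 2.0)) * 2
    out = np.zeros((len(stack), newB, newB), dtype=np.float32)
    for i, img in enumerate(stack.images):
        z = ndimage.zoom(img, factor, order=1)
        s = z.shape[0]
        if s >= newB:
            a = (s - newB) // 2
            out[i] = z[a:a + newB, a:a + newB]
        else:
            a = (newB - s) // 2
            out[i, a:a + s, a:a + s] = z
    rec = stack.records.copy()
    if "xshift_px" in rec:
        rec["xshift_px"] = rec["xshift_px"] * factor
    return SegmentStack(out, new_pixel, rec, stack.seed, dict(stack.meta))
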