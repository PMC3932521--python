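"""Helical diffraction indexing.

The Fourier transform of a helical filament is confined to discrete layer
lines whose axial position Z and first radial intensity maximum R encode
the lattice: intensity along a layer line follows a Bessel function J_n,
and the first maximum of J_n falls at argument x_n, so n is recoverable
from R via x_n ~= 2 pi R r_fil.  Meridional lines (n = 0) peak on the
axis; the lowest-order meridional spacing estimates the axial rise.

The sign of n (handedness) is not knowable from projection power spectra
and is never assigned here; see :mod:`helixforge.dockchir`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .heligeom import HelicalSymmetry
from .synthgen import SegmentStack
from ._fourier import cfft2

logger = logging.getLogger(__name__)

__all__ = [
    "PowerSpectrum",
    "bessel_first_max",
    "center_segments",
    "sum_power",
    "index_layer_lines",
    "rise_from_meridional",
    "test_start_number",
]


@dataclass
class PowerSpectrum:
    """Summed 2D power spectrum, DC at the center; rows are axial
    frequency (filament axis), columns radial frequency."""

    power: np.ndarray
    pixel: float

    @property
    def box(self) -> int:
        return self.power.shape[0]

    @property
    def freq_step(self) -> float:
        """One Fourier pixel in 1/Angstrom."""
        return 1.0 / (self.box * self.pixel)

    def display(self) -> np.ndarray:
        """Square-root transform for display of weak high-resolution
        layer lines."""
        return np.sqrt(np.maximum(self.power, 0.0))


@lru_cache(maxsize=64)
def bessel_first_max(n: int) -> float:
    """Argument of the first maximum of J_n, by numeric maximization."""
    if n < 0:
        raise ValueError("order must be >= 0")
    if n == 0:
        return 0.0
    # the first max of J_n lies between n and the first zero j_{n,1}
    hi = float(special.jn_zeros(n, 1)[0])
    res = optimize.minimize_scalar(
        lambda x: -special.jv(n, x), bounds=(max(n * 0.5, 1e-6), hi), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def center_segments(
    stack: SegmentStack,
    reference: np.ndarray,
    max_shift: Optional[int] = None,
) -> tuple[SegmentStack, np.ndarray]:
    """Center each segment horizontally against a reference projection.

    The best x-shift by cross-correlation is rounded to the nearest
    integer and applied (circularly); the vertical direction is left
    untouched.  A correlation peak at the search-window edge flags the
    segment, which is then not shifted.
    """
    B = stack.box
    if reference.shape != (B, B):
        raise ValueError("reference must match the stack box size")
    if max_shift is None:
        max_shift = B // 4
    Fr = np.fft.fft(reference - reference.mean(), axis=1)
    shifts = np.zeros(len(stack), dtype=int)
    flagged = np.zeros(len(stack), dtype=bool)
    out = stack.images.copy()
    for i, img in enumerate(stack.images):
        Fs = np.fft.fft(img - img.mean(), axis=1)
        corr = np.fft.ifft(Fs * np.conj(Fr), axis=1).real.sum(axis=0)
        corr = np.fft.fftshift(corr)
        c = B // 2
        window = corr[c - max_shift:c + max_shift + 1]
        k = int(np.argmax(window))
        if k == 0 or k == len(window) - 1:
            flagged[i] = True
            continue
        d = k - max_shift  # segment displaced by +d relative to reference
        shifts[i] = -d
        out[i] = np.roll(img, -d, axis=1)
    rec = stack.records.copy()
    rec["centered_shift_px"] = shifts
    rec["center_flagged"] = flagged
    centered = SegmentStack(out, stack.pixel, rec, stack.seed, dict(stack.meta))
    return centered, shifts


def sum_power(stack: SegmentStack) -> PowerSpectrum:
    """Average power spectrum of all (centered) segments, DC centered."""
    if len(stack) == 0:
        raise ValueError("empty stack")
    acc = np.zeros((stack.box, stack.box))
    for img in stack.images:
        acc += np.abs(cfft2(img - img.mean())) ** 2
    return PowerSpectrum(acc / len(stack), stack.pixel)


def _axial_profile(power: np.ndarray) -> np.ndarray:
    """Max-over-radius intensity per axial frequency row, folding the
    +-Z halves; index i corresponds to axial frequency i Fourier pixels."""
    B = power.shape[0]
    c = B // 2
    folded = []
    for i in range(0, c):
        rows = [power[c + i]]
        if i > 0:
            rows.append(power[c - i])
        folded.append(np.mean(rows, axis=0))
    return np.array(folded)  # (c, B) rows by axial index


def index_layer_lines(
    power: PowerSpectrum,
    filament_radius: float,
    max_order: int = 14,
    k_mad: float = 5.0,
    meridional_px: float = 1.5,
    exclude_equator_px: int = 2,
) -> pd.DataFrame:
    """Detect layer lines and assign Bessel orders.

    A layer line is an axial local maximum of the max-over-radius profile
    exceeding median + ``k_mad`` * MAD of its neighborhood.  A line is
    meridional (n = 0) when the on-axis intensity (within
    ``meridional_px`` of the meridian) is itself an axial local maximum
    there — J_n(0) = 0 for every n != 0, so only n = 0 lines carry
    on-axis power.  Other lines get the order minimizing
    ``|x_n - 2 pi r_peak filament_radius|`` over n in [0, max_order],
    where r_peak is the first radial intensity maximum and x_n the first
    maximum of J_n.  The sign of n is left unresolved.  ``ll_index``
    numbers lines relative to the smallest detected axial spacing.

    Sub-pixel axial positions: meridional lines behave as a pure axial
    tone boxed by the segment window, so the two-bin |sinc|^2 estimator
    is used on the on-axis profile; other lines use a parabolic fit.
    """
    if filament_radius <= 0:
        raise ValueError("filament_radius must be positive")
    prof2d = _axial_profile(power.power)
    c = power.box // 2
    profile = prof2d.max(axis=1)
    profile[:exclude_equator_px] = 0.0  # equator/DC region
    mer_lo = int(c - meridional_px)
    mer_hi = int(math.ceil(c + meridional_px)) + 1
    axis_prof = prof2d[:, mer_lo:mer_hi].max(axis=1)
    axis_prof[:exclude_equator_px] = 0.0

    # per-row annulus statistics: a layer line occupies few pixels, so the
    # row median/MAD estimate the noise floor robustly
    med_row = np.median(prof2d, axis=1)
    mad_row = np.median(np.abs(prof2d - med_row[:, None]), axis=1)
    sigma_row = 1.4826 * mad_row + 1e-30
    signif = (profile - med_row) / sigma_row

    is_peak = np.zeros(len(profile), dtype=bool)
    axis_peak = np.zeros(len(profile), dtype=bool)
    for i in range(exclude_equator_px, len(profile) - 1):
        local_max = profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
        if local_max and signif[i] > k_mad:
            is_peak[i] = True
        if is_peak[i] and axis_prof[i] >= axis_prof[i - 1] \
                and axis_prof[i] >= axis_prof[i + 1] \
                and axis_prof[i] >= 0.5 * profile[i]:
            # the on-axis power must carry a large share of the line: the
            # x-boxing sinc leaks off-axis maxima onto the axis, but only
            # weakly (J_n(0) = 0 for n != 0)
            axis_peak[i] = True
    rows = []
    for i in np.nonzero(is_peak | axis_peak)[0]:
        meridional = bool(axis_peak[i])
        if meridional and 1 <= i < len(axis_prof) - 1:
            # two-bin |sinc|^2 interpolation toward the larger neighbor,
            # after subtracting the local background level
            bg = ndimage.median_filter(axis_prof, size=15, mode="nearest")[i]
            y0 = max(axis_prof[i] - bg, 1e-30)
            yp = max(axis_prof[i + 1] - bg, 0.0)
            ym = max(axis_prof[i - 1] - bg, 0.0)
            if yp >= ym:
                ratio = math.sqrt(yp / y0)
                delta = ratio / (1.0 + ratio)
            else:
                ratio = math.sqrt(ym / y0)
                delta = -ratio / (1.0 + ratio)
            delta = float(np.clip(delta, -0.5, 0.5))
        elif 1 <= i < len(profile) - 1:
            ym, y0, yp = profile[i - 1], profile[i], profile[i + 1]
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if abs(denom) > 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        line = prof2d[i].copy()
        # fold +-radial halves around the meridian
        folded = np.array([
            0.5 * (line[c + r] + line[c - r]) if r > 0 else line[c]
            for r in range(0, c)
        ])
        r_px = int(np.argmax(folded))
        r_sub = float(r_px)
        if 1 <= r_px < len(folded) - 1:
            ym, y0, yp = folded[r_px - 1], folded[r_px], folded[r_px + 1]
            den = ym - 2 * y0 + yp
            if abs(den) > 0:
                r_sub = r_px + float(np.clip(0.5 * (ym - yp) / den, -0.5, 0.5))
        r_peak = r_sub * power.freq_step
        z_star = (i + delta) * power.freq_step
        if meridional or r_px < meridional_px:
            n = 0
            r_peak = r_peak if r_px < meridional_px else 0.0
        else:
            x_target = 2.0 * math.pi * r_peak * filament_radius
            errs = [abs(bessel_first_max(n) - x_target) for n in range(max_order + 1)]
            n = int(np.argmin(errs))
        rows.append(dict(z_star=z_star, r_peak=r_peak, bessel_n=n, axial_px=i))
    if not rows:
        logger.warning("no layer lines detected")
        return pd.DataFrame(columns=["ll_index", "z_star", "r_peak", "bessel_n"])
    df = pd.DataFrame(rows).sort_values("z_star").reset_index(drop=True)
    base = df["z_star"].iloc[0]
    df["ll_index"] = np.round(df["z_star"] / base).astype(int)
    return df[["ll_index", "z_star", "r_peak", "bessel_n", "axial_px"]]


def rise_from_meridional(table: pd.DataFrame) -> float:
    """Axial rise (Angstrom) from the lowest-frequency meridional layer
    line: rise = 1 / Z* of the first n = 0 row."""
    mer = table[table["bessel_n"] == 0]
    if len(mer) == 0:
        raise ValueError("no meridional (n = 0) layer line in the table")
    z = float(mer["z_star"].min())
    return 1.0 / z


def test_start_number(
    stack: SegmentStack,
    candidates: Sequence[int],
    init: HelicalSymmetry,
    short_iters: int = 8,
    reference_radius: Optional[float] = None,
    align_params=None,
    rise_meridional: Optional[float] = None,
) -> pd.DataFrame:
    """Short IHRSR refinement per start-number hypothesis.

    Each candidate (signed start number, the sign selecting the mirror)
    runs ``short_iters`` refinement cycles from a cylinder; the report
    holds the converged (twist, rise), the mean alignment correlation,
    and a flag for candidates whose converged rise disagrees with the
    meridional rise estimate by more than one Fourier pixel.  The correct
    start number converges to a rise consistent with the meridional; a
    wrong one does not (or scores lower).
    """
    from .ihrsr import run_ihrsr, AlignParams

    if len(candidates) == 0:
        raise ValueError("no candidates")
    if rise_meridional is None:
        centered, _ = center_segments(stack, _cylinder_proj(stack))
        table = index_layer_lines(
            sum_power(centered),
            filament_radius=reference_radius or 45.0,
        )
        try:
            rise_meridional = rise_from_meridional(table)
        except ValueError:
            rise_meridional = None
    rows = []
    fourier_px = 1.0 / (stack.box * stack.pixel)
    for cand in candidates:
        n = abs(int(cand))
        sign = -1.0 if cand < 0 else 1.0
        cand_init = HelicalSymmetry(sign * abs(init.twist), init.rise, n)
        ap = align_params
        if ap is None:
            ap = AlignParams(azimuth_max=360.0 / n)
        try:
            state = run_ihrsr(stack, cand_init, max_iters=short_iters, align_params=ap)
            twist, rise = state.symmetry.twist, state.symmetry.rise
            corr = float(state.trace["mean_corr"].iloc[-1])
            flag = False
            if rise_meridional is not None:
                flag = abs(1.0 / rise - 1.0 / rise_meridional) > fourier_px
            rows.append(dict(candidate=cand, n_start=n, twist=twist, rise=rise,
                             mean_corr=corr, rise_inconsistent=flag, error=""))
        except Exception as exc:  # propagate per candidate, don't abort others
            rows.append(dict(candidate=cand, n_start=n, twist=np.nan, rise=np.nan,
                             mean_corr=np.nan, rise_inconsistent=True, error=str(exc)))
    return pd.DataFrame(rows)


def _cylinder_proj(stack: SegmentStack, diameter: float = 90.0) -> np.ndarray:
    from .ihrsr import cylinder_reference
    from .synthgen import project

    ref = cylinder_reference(diameter, stack.box, stack.pixel)
    return project(ref, 0.0)
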