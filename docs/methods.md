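# Methods

This note records the models, conventions, and numerical choices behind
helixforge, and what the synthetic-data studies do and do not establish.

## Helical lattice model

A filament is parameterized by per-subunit twist ΔΦ (degrees, signed),
rise Δz (Å, positive) and start number n ≥ 1. Sign convention: positive
twist means azimuth increases with +z in a right-handed frame (a
right-handed helix); the CARD-like filament is stored as ΔΦ = −53.6°.
Angles are normalized to (−180°, 180°]; azimuths are reported in
[0°, 360°). Subunit (layer k, strand j) sits at z = k·Δz, azimuth
k·ΔΦ + j·360/n. Mirroring flips the twist sign and nothing else.
Subunit counts over a length L are round-half-up of L/Δz·n, matching the
convention "≈720 subunits per 400 nm" at Δz = 16.7 Å.

## Synthetic data

The subunit template is a set of Gaussian blobs (offset, amplitude,
sigma) anchored at the strand radius. The default template is three
short rods of three blobs each (σ 3–3.5 Å), deliberately non-coplanar
with the axis so the filament is chiral and handedness experiments are
meaningful; the "decorated" variant adds three fragmented blobs ~15 Å
radially outside the core, emulating a filament with a loose outer
density sheet. Outer diameter of the thresholded default filament is
≈90 Å at a 32 Å strand radius.

Segments are rendered analytically: the projection of a 3D Gaussian
along any direction is a 2D Gaussian of the same sigma, so each boxed
segment is an exact closed-form sum over lattice blobs — independent of
the volume-interpolation projector used for references during
refinement, which avoids testing the reconstruction against its own
forward model. Per segment the generator draws a uniform azimuth, a
uniform out-of-plane tilt (default ±10°), an in-plane angle (default
±5°), a sub-pixel horizontal shift (default ±3 px), and the axial
lattice phase implied by the boxing position. Noise is additive white
Gaussian; the SNR convention is signal variance / noise variance.
Overlapping segments of one filament share the noise of their common
pixels (noise is drawn per filament as a tall canvas and windowed per
segment), as happens when boxes are cut from one micrograph — this is
what makes filament-level half-set splitting strictly more independent
than segment-level splitting. Not simulated: structural noise (carbon,
ice gradients), detector MTF, astigmatism, beam-induced motion,
radiation damage, filament bending, negative stain. Passing tests
therefore demonstrate correctness of the algorithms under an idealized
rigid-lattice image model, not performance on real micrographs.

CTF: χ(s) = πλΔf·s² − (π/2)C<sub>s</sub>λ³s⁴, CTF = −(√(1−A²)·sin χ +
A·cos χ), underfocus positive. Modes: apply, phase-flip (sign only),
Wiener (CTF/(CTF²+c), default c = 0.2 ≡ 1/SNR at SNR 5).

## Indexing

Power spectra are averaged over X-centered segments (integer-pixel
centering against a cylinder projection, ±box/4 search window). Layer
lines are axial local maxima of the max-over-radius profile exceeding
median + 5·MAD of their own row's annulus statistics (a pure-noise
stack yields an empty table under this rule). A line is meridional when
its on-axis intensity (within 1.5 Fourier pixels of the meridian) is an
axial local maximum carrying at least half the row maximum — J_n(0) = 0
for n ≠ 0, and the factor 0.5 tolerates the off-axis leakage introduced
by the finite filament width in x. Meridional sub-pixel positions use
the two-bin |sinc|² estimator (the line behaves as a boxed pure tone)
after local background subtraction; other lines use a parabolic fit.
Bessel orders minimize |x_n − 2πR·r_peak| with x_n the numerically
located first maximum of J_n; the sign of n (handedness) is never
inferred from projections. High orders (≳11 at a 128-px box) are ±1
ambiguous because adjacent first-maximum radii fall within the radial
resolution — the same ambiguity that historically left 3- vs 4-start
assignment to refinement, which is exactly how `test_start_number`
resolves it (short refinements per candidate, flagging rises
inconsistent with the meridional estimate by more than one Fourier
pixel).

## IHRSR

Conventions: volumes are numpy (z, y, x) with the helical axis on z and
origin at N//2; images are (v, u) with the filament axis vertical;
orientations are R = R_y(in-plane)·R_x(tilt)·R_z(azimuth); all rotations
right-handed.

*Alignment.* Reference projections are central slices of the 3D
transform (projection-slice theorem, trilinear interpolation on the
centered FFT). The search grid covers azimuth (default 4°, one 360/n
sector), out-of-plane tilt (0, ±2…±14° for range 15 at step 2, per the
refinement protocol), in-plane angle (default ±6° at 2°), integer
horizontal shifts (±8 px), and the axial lattice phase as five sub-pixel
vertical shifts spanning one rise, applied to the slices as phase ramps.
Scores are normalized cross-correlation with means removed (DC zeroed);
the whole grid is evaluated as batched complex GEMMs over the
column-frequency axis. Note the azimuth of one segment is only
determined modulo the lattice relation (az, Δv) ≡ (az − ΔΦ, Δv + Δz):
equivalent solutions insert identical data.

*Reconstruction.* Direct Fourier inversion: each aligned segment
(in-plane rotated back, shifts removed as phase ramps) is gridded into
the 3D transform as a central slice with trilinear weights; weight
normalization (ε = 10⁻⁶) compensates anisotropic azimuth coverage.

*Symmetry search.* The volume is resampled once onto a cylindrical grid
(r, φ, z) and transformed over (φ, z). Averaging over the C_n rotations
cancels all angular harmonics except multiples of n, so the correlation
between a centrally windowed copy of the volume and the average of its
helically transformed copies reduces to a phase-weighted sum over the
reduced cross-spectrum — exact for the resampled volume and cheap
enough for a dense (twist, rise) scan with step refinement
0.5 → 0.1 → 0.02 (° and Å). The central z-window (cosine-tapered, half
height) keeps all shifted copies inside real data, so the score is
unbiased in rise. Optima pinned to a bounds edge are flagged. A
brute-force oracle (explicit real-space transform + correlation) backs
this in the tests.

*Imposition.* Real-space averaging over every helical operation whose
translated copy overlaps ≥ 60% of the volume height, plus the C_n
rotations, with per-plane weights. Linear interpolation attenuates
voxel-scale features by a few percent per pass; this limits contrast,
not the recovered symmetry parameters.

*Loop.* align → backproject → search → impose, from a soft-edged 90 Å
cylinder. The iteration-0 reconstruction, aligned against a featureless
cylinder, carries no reliable lattice, so the initial symmetry is held
for one iteration before searching begins; convergence is declared when
twist and rise move < 0.05 (° / Å) over 5 consecutive iterations. The
1.0 Å mid-run rise perturbation protocol is built in (`perturb=`).
Known limitation: with a poor initialization the loop can settle into a
self-consistent wrong attractor (reference bias); such solutions show
visibly lower mean alignment correlation, and the start-number test
exposes them through meridional inconsistency. Initializations within a
few degrees / ~1.5 Å (as provided by indexing) converge correctly in
all studied conditions.

*Sorting.* 3×3 (twist × rise) bin grid centered on the current
symmetry, default steps 2.0° × 1.5 Å; each segment is assigned to the
bin whose symmetrized reference it correlates with best. The 3×3
reading of "nine bins" is a design choice; the original arrangement is
not recorded.

## Validation

Half-sets are split at the level of whole filaments (never segments) by
greedy count balancing. Volume alignment searches axial rotation ×
axial shift on the full correlation surface computed in cylindrical
coordinates, with quadratic sub-pixel refinement. FSC uses one-voxel
shells; resolution is the first crossing below 0.5 (linear
interpolation); a never-crossing curve returns Nyquist with a flag. The
0.5 threshold follows the source protocol, which distrusted 0.143 for
nearly identically symmetrized half-maps. Amplitude correction:
B-factor exp(−B·s²/4) or division by the average |CTF| envelope floored
at 0.1 of peak, both followed by a two-voxel cosine-edge low-pass.

## Handedness

Docking renders the blob template at candidate poses (z-y-z Euler grid,
default 15° coarse / 3° fine, Nelder–Mead translation polish) and
scores normalized correlation against the map on probe points around
the template footprint. `call_handedness` docks into the map and its
exact mirror (reflection about the center voxel through the plane
containing the axis and the first grid axis); the better-scoring side
confirms or flips the map's nominal hand, with the score margin as
confidence (margins below 0.01 are "undetermined"). Any initial
placement is mirrored along with the map. Automatic full 6-D docking of
a subunit into a filament map is out of scope: as in practice, a rough
initial placement in density (at the strand radius) precedes local
optimization. Achirality of a template is detected by exhaustively
rotating its mirror image onto itself (Gaussian-overlap score) and
rejected with an error.

## Rod-length quantification

Lengths are drawn from a Gaussian truncated below the imaging
resolution limit (defaults n = 74, mean 400 nm, sd 150 nm, cutoff
100 nm; bin width 50 nm). The histogram is fit by least-squares
Gaussian; FWHM = 2√(2 ln 2)·σ. The truncation biases the *sample* mean
upward while the histogram fit, seeing the intact right flank, recovers
the underlying peak — the reason the figure-style analysis fits rather
than averages. A degenerate histogram falls back to sample statistics
with a warning. (The source text calls the observed distribution
"Poisson" while fitting a Gaussian in the figure; the Gaussian reading
is implemented.)

## Problem sizes

The bundled studies run at desk scale: IHRSR recovery uses ~300
segments of 100 px at 4.52 Å/px (a 2×-binned analogue of 200 px at
2.26 Å), a 100³ volume, and converges in ~10–15 iterations (~4 min on
one CPU); indexing uses 192 segments of 128 px at 2.26 Å/px; docking
grids are 30°/10° in the tests. Full-scale parameters (box 200 at
2.26 Å, finer grids) are plain arguments throughout.
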