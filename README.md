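# helixforge

Tools for the cryo-EM analysis of helical protein filaments, built around
the workflow that solved the MAVS CARD filament: simulate boxed filament
segments with known ground truth, index their helical diffraction, refine
the helical symmetry by iterative real-space refinement (IHRSR), validate
the map by Fourier shell correlation, determine handedness by mirror
docking, and quantify filament geometry.

## The problem

A helical filament is a one-dimensional crystal: each subunit is related
to the next within a strand by an azimuthal rotation ΔΦ (the *twist*) and
an axial translation Δz (the *rise*); an *n*-start filament carries *n*
intertwined strands related by C<sub>n</sub> rotation about the axis.
The MAVS CARD filament is a left-handed 3-start helix with
ΔΦ = 53.6°, Δz = 16.8 Å, so one turn of a strand holds
360/53.6 ≈ 6.7 subunits and a 400 nm filament ≈ 720 subunits across its
three strands.

Electron micrographs give noisy 2D projections of unknown orientation.
The pipeline recovers the 3D structure in stages:

1. **Indexing** (`helixforge.layerlines`) — the Fourier transform of a
   helix is confined to layer lines; intensity along the line at axial
   frequency Z(n, m) = (n·ΔΦ/360 + m)/Δz follows a Bessel function
   J<sub>n</sub>, and the first maximum of J<sub>n</sub> at radius R
   satisfies x<sub>n</sub> ≈ 2πR·r<sub>fil</sub>. Meridional lines
   (n = 0) read off the rise directly.
2. **IHRSR** (`helixforge.ihrsr`) — alternate projection matching of
   boxed segments against reference projections, 3D reconstruction,
   a search for the (ΔΦ, Δz) maximizing the reconstruction's
   self-consistency under its own symmetry, and imposition of that
   symmetry to form the next reference. Started from a featureless
   cylinder, the parameters converge to the filament lattice.
3. **Validation** (`helixforge.mapval`) — filament-disjoint half-set
   reconstructions, FSC at the 0.5 threshold, CTF-envelope and
   B-factor amplitude correction (exp(−B·s²/4), B < 0 sharpens).
4. **Handedness** (`helixforge.dockchir`) — projections cannot tell a
   helix from its mirror; docking a chiral subunit template into the map
   and its mirror breaks the tie.
5. **Quantification** (`helixforge.quantsim`, `helixforge.heligeom`) —
   lattice statistics and rod-length distributions (truncated-Gaussian
   simulation, histogram + Gaussian fit).

`helixforge.synthgen` generates all test data: Gaussian-blob subunits on
an exact helical lattice, rendered analytically into noisy, optionally
CTF-modulated, 90%-overlapping boxed segments with full ground truth.

## Worked example

```python
from helixforge import HelicalSymmetry, card_template, simulate_segments
from helixforge.ihrsr import run_ihrsr
from helixforge import presets

sym = HelicalSymmetry(twist=-53.6, rise=16.8, n_start=3)
stack = simulate_segments(sym, card_template(), n_filaments=30, length=190,
                          box=100, overlap=0.9, snr=0.2, seed=11,
                          pixel=4.52, radius=32.0)
state = run_ihrsr(stack, HelicalSymmetry(-50.0, 15.5, 3),
                  align_params=presets.desk_align_params(3),
                  max_iters=30, cylinder_diameter=90.0)
print(f"twist {abs(state.symmetry.twist):.2f} deg, "
      f"rise {state.symmetry.rise:.2f} A, converged={state.converged}")
```

prints

```
twist 53.60 deg, rise 16.78 A, converged=True
```

— starting 3.6° and 1.3 Å away from the truth, the refinement of 300
noisy segments (signal-to-noise 0.2) converges onto the generating
symmetry within a tenth of a degree and a few hundredths of an Ångström.

The same stages are scriptable from the shell:

```
helixforge simulate --config sim.yaml --out run/
helixforge index    --config idx.yaml --out run/
helixforge refine   --config ref.yaml --out run/
```

Each stage writes its artifacts (MRC volumes/stacks, TSV tables) and a
machine-readable `summary.json`.

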