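"""IHRSR machinery: references, alignment, reconstruction, symmetry
search/imposition, and the full refinement loop at mini scale."""

import numpy as np
import pandas as pd
import pytest

from helixforge import heligeom as hg
from helixforge import synthgen as sg
from helixforge import ihrsr
from helixforge.ihrsr import _helical_op

from conftest import lattice_equivalent_azimuth_error, MINI_VOXEL, MINI_BOX


class TestCylinderReference:
    def test_radius_in_voxels(self):
        ref = ihrsr.cylinder_reference(90.0, 96, 2.26)
        mid = ref.grid[48]
        c = 48
        y, x = np.meshgrid(np.arange(96) - c, np.arange(96) - c, indexing="ij")
        r = np.sqrt(x ** 2 + y ** 2)
        edge = r[mid >= 0.5].max()
        assert edge == pytest.approx(90.0 / 2 / 2.26, abs=1.5)  # ~19.9 voxels

    def test_projection_azimuth_independent(self):
        ref = ihrsr.cylinder_reference(90.0, 64, 4.52)
        p0 = sg.project(ref, azimuth=0.0)
        p1 = sg.project(ref, azimuth=73.0)
        # bilinear resampling at the soft edge leaves a few-percent residue
        assert np.allclose(p0, p1, atol=0.05 * np.abs(p0).max())

    def test_integrated_density_matches_analytic(self):
        grid, voxel, diam = 64, 4.52, 90.0
        ref = ihrsr.cylinder_reference(diam, grid, voxel)
        total = ref.grid.sum() * voxel ** 3
        analytic = np.pi * (diam / 2) ** 2 * (grid * voxel)
        assert total == pytest.approx(analytic, rel=0.02)

    def test_oversized_cylinder_rejected(self):
        with pytest.raises(ValueError):
            ihrsr.cylinder_reference(400.0, 64, 4.52)


@pytest.fixture(scope="module")
def aligned(clean_stack, card_reference, card_sym, mini_align_params):
    return ihrsr.align_to_reference(
        clean_stack, card_reference, params=mini_align_params,
        rise_px=card_sym.rise / MINI_VOXEL,
    )


class TestAlignment:

    def test_azimuth_recovered_modulo_lattice(self, aligned, clean_stack, card_sym,
                                              mini_align_params):
        err = lattice_equivalent_azimuth_error(
            clean_stack.records["azimuth"], aligned["azimuth"], card_sym)
        assert np.median(err) <= mini_align_params.azimuth_step / 2 + 0.5
        assert err.max() <= mini_align_params.azimuth_step

    def test_tilt_recovered_within_step(self, aligned, clean_stack, mini_align_params):
        d = np.abs(clean_stack.records["tilt"].to_numpy() - aligned["tilt"].to_numpy())
        assert d.max() <= mini_align_params.tilt_step

    def test_inplane_recovered_within_step(self, aligned, clean_stack, mini_align_params):
        d = np.abs(clean_stack.records["inplane"].to_numpy() - aligned["inplane"].to_numpy())
        assert d.max() <= mini_align_params.inplane_step

    def test_xshift_matches_bruteforce(self, aligned, clean_stack, card_reference,
                                       mini_align_params):
        """For fixed best orientation, the integer x-shift equals the
        exhaustive-scan argmax."""
        from helixforge._fourier import cfftn, extract_slices, view_matrix, cfft2, shift_phase

        VF = cfftn(card_reference.grid)
        i = 7
        row = aligned.iloc[i]
        R = view_matrix(row["azimuth"], row["tilt"], 0.0)
        sl = extract_slices(VF, R[None])[0]
        sl = sl * shift_phase(MINI_BOX, 0.0, row["yshift_px"])
        proj = np.real(np.fft.ifft2(np.fft.ifftshift(sl)))
        proj = np.fft.fftshift(proj)
        img = ihrsr._rotate_image(clean_stack.images[i], -row["inplane"])
        img = img - img.mean()
        proj = proj - proj.mean()
        scores = {d: float(np.sum(np.roll(img, -d, axis=1) * proj))
                  for d in range(-mini_align_params.max_shift_px,
                                 mini_align_params.max_shift_px + 1)}
        best = max(scores, key=scores.get)
        assert int(row["xshift_px"]) == pytest.approx(best, abs=1)

    def test_all_zero_segment_flagged(self, card_reference, mini_align_params, clean_stack):
        imgs = np.zeros((1, MINI_BOX, MINI_BOX), dtype=np.float32)
        rec = pd.DataFrame({"filament": [0], "segment": [0]})
        stack = sg.SegmentStack(imgs, MINI_VOXEL, rec, 0)
        al = ihrsr.align_to_reference(stack, card_reference, params=mini_align_params)
        assert al.iloc[0]["corr"] == 0.0 and bool(al.iloc[0]["flagged"])


class TestBackproject:
    def test_roundtrip_fidelity(self, card_reference):
        """Noise-free projections at fine azimuth sampling reconstruct
        the volume beyond 1/(3 voxel) (FSC at 0.5)."""
        from helixforge.mapval import fsc_resolution

        azs = np.arange(0.0, 360.0, 3.0)
        imgs = np.stack([sg.project(card_reference, a) for a in azs]).astype(np.float32)
        rec = pd.DataFrame({"filament": np.zeros(len(azs), int), "segment": np.arange(len(azs))})
        stack = sg.SegmentStack(imgs, MINI_VOXEL, rec, 0)
        al = pd.DataFrame(dict(azimuth=azs, tilt=0.0, inplane=0.0,
                               xshift_px=0, yshift_px=0.0, corr=1.0, flagged=False))
        vol = ihrsr.backproject(stack, al)
        _, res, _ = fsc_resolution(card_reference, vol, 0.5)
        assert res < 3 * MINI_VOXEL

    def test_duplicates_do_not_change_volume(self, card_reference):
        azs = np.arange(0.0, 360.0, 30.0)
        imgs = np.stack([sg.project(card_reference, a) for a in azs]).astype(np.float32)
        rec = pd.DataFrame({"filament": np.zeros(len(azs), int), "segment": np.arange(len(azs))})
        al = pd.DataFrame(dict(azimuth=azs, tilt=0.0, inplane=0.0,
                               xshift_px=0, yshift_px=0.0, corr=1.0, flagged=False))
        v1 = ihrsr.backproject(sg.SegmentStack(imgs, MINI_VOXEL, rec, 0), al)
        imgs2 = np.concatenate([imgs, imgs])
        rec2 = pd.DataFrame({"filament": np.zeros(2 * len(azs), int),
                             "segment": np.arange(2 * len(azs))})
        al2 = pd.concat([al, al], ignore_index=True)
        v2 = ihrsr.backproject(sg.SegmentStack(imgs2, MINI_VOXEL, rec2, 0), al2)
        cc = np.corrcoef(v1.grid.ravel(), v2.grid.ravel())[0, 1]
        assert cc > 0.9999

    def test_mismatched_alignments_rejected(self, clean_stack):
        with pytest.raises(ValueError):
            ihrsr.backproject(clean_stack, pd.DataFrame(dict(azimuth=[0.0])))


class TestSearchSymmetry:
    def test_exact_volume_recovers_truth(self, card_volume, card_sym):
        got, score, edge = ihrsr.search_symmetry(
            card_volume, hg.HelicalSymmetry(-50.0, 15.5, 3), bounds=(5.0, 2.5))
        assert not edge
        assert abs(got.twist) == pytest.approx(53.6, abs=0.05)
        assert got.rise == pytest.approx(16.8, abs=0.05)

    def test_matches_bruteforce_grid(self, card_volume):
        """The analytic cylindrical score ranks a coarse (twist, rise)
        grid identically to explicit real-space symmetrization."""
        twists = [-55.6, -54.6, -53.6, -52.6, -51.6]
        rises = [15.8, 16.3, 16.8, 17.3]
        spec = ihrsr._CylSpectrum(card_volume)
        g = card_volume.grid
        lo, hi = 16, 48

        def brute(tw, ri):
            # HSEARCH-style: correlation with the singly-transformed copy
            t = _helical_op(g, tw, ri / card_volume.voxel)
            return np.corrcoef(g[lo:hi].ravel(), t[lo:hi].ravel())[0, 1]

        analytic = np.array([[spec.score(t, r, 3) for r in rises] for t in twists])
        brutef = np.array([[brute(t, r) for r in rises] for t in twists])
        assert np.unravel_index(np.argmax(analytic), analytic.shape) == \
               np.unravel_index(np.argmax(brutef), brutef.shape)
        # rank agreement beyond the argmax
        from scipy.stats import spearmanr

        rho = spearmanr(analytic.ravel(), brutef.ravel()).statistic
        assert rho > 0.8

    def test_edge_optimum_flagged(self, card_volume):
        _, _, edge = ihrsr.search_symmetry(
            card_volume, hg.HelicalSymmetry(-45.0, 16.8, 3), bounds=(2.0, 0.5))
        assert edge

    def test_mirror_scores_lower_on_chiral_volume(self, card_volume, card_sym):
        spec = ihrsr._CylSpectrum(card_volume)
        s_true = spec.score(card_sym.twist, card_sym.rise, 3)
        s_mirror = spec.score(-card_sym.twist, card_sym.rise, 3)
        assert s_true > s_mirror + 0.1


class TestImposeSymmetry:
    def test_symmetric_volume_nearly_unchanged(self, card_sym):
        """On a volume whose features are resolved at the voxel scale,
        imposing the generating symmetry changes little (the residue is
        pure interpolation smoothing)."""
        smooth = sg.SubunitTemplate((
            ((0.0, 0.0, 0.0), 1.0, 8.0),
            ((6.0, -4.0, 5.0), 0.8, 7.0),
            ((-5.0, 6.0, -4.0), 0.8, 7.0),
        ))
        vol = sg.build_volume(card_sym, smooth, radius=32.0, grid=MINI_BOX,
                              voxel=MINI_VOXEL)
        out = ihrsr.impose_symmetry(vol, card_sym)
        lo, hi = 16, 48
        ref_rms = np.sqrt(np.mean(vol.grid[lo:hi] ** 2))
        rms = np.sqrt(np.mean((out.grid[lo:hi] - vol.grid[lo:hi]) ** 2))
        # residue is the linear-interpolation attenuation of the
        # fractional-voxel axial shifts (~5% for voxel-scale features)
        assert rms < 0.08 * ref_rms

    def test_c3_imposition_builds_rotational_symmetry(self):
        rng = np.random.default_rng(1)
        vol = sg.DensityVolume(
            np.asarray(np.maximum(rng.normal(size=(32, 32, 32)), 0.0)), 4.0)
        sym = hg.HelicalSymmetry(120.0, 100.0, 3)  # rise larger than height: pure C3
        out = ihrsr.impose_symmetry(vol, sym)

        def c3_selfcorr(v):
            r = _helical_op(v.grid, 120.0, 0.0)
            return np.corrcoef(v.grid[4:28].ravel(), r[4:28].ravel())[0, 1]

        assert c3_selfcorr(out) > 3 * max(c3_selfcorr(vol), 0.05)

    def test_mirror_imposition_degrades_chiral_volume(self, card_volume, card_sym):
        right = ihrsr.impose_symmetry(card_volume, card_sym)
        wrong = ihrsr.impose_symmetry(card_volume, hg.mirror(card_sym))
        lo, hi = 16, 48
        c_right = np.corrcoef(card_volume.grid[lo:hi].ravel(), right.grid[lo:hi].ravel())[0, 1]
        c_wrong = np.corrcoef(card_volume.grid[lo:hi].ravel(), wrong.grid[lo:hi].ravel())[0, 1]
        assert c_wrong < c_right - 0.1

    def test_undersampled_rise_rejected(self, card_volume):
        with pytest.raises(ValueError):
            ihrsr.impose_symmetry(card_volume, hg.HelicalSymmetry(-53.6, 2.0, 3))


class TestRunIHRSR:
    def test_recovers_symmetry_from_cylinder(self, noisy_stack, mini_align_params):
        state = ihrsr.run_ihrsr(
            noisy_stack, hg.HelicalSymmetry(-50.0, 15.5, 3), max_iters=18,
            align_params=mini_align_params, search_bounds=(2.0, 1.2),
        )
        assert state.converged
        assert abs(state.symmetry.twist) == pytest.approx(53.6, abs=0.3)
        assert state.symmetry.rise == pytest.approx(16.8, abs=0.2)
        # correlation is near-monotone once structure has emerged
        mc = state.trace["mean_corr"].to_numpy()
        assert np.all(np.diff(mc[2:]) > -1e-3)

    def test_trace_bookkeeping(self, noisy_stack, mini_align_params):
        state = ihrsr.run_ihrsr(
            noisy_stack, hg.HelicalSymmetry(-53.6, 16.8, 3), max_iters=3,
            align_params=mini_align_params,
        )
        assert len(state.trace) == state.iteration + 1
        assert not state.converged  # 3 iterations cannot satisfy the 5-iter window

    def test_empty_stack_rejected(self, noisy_stack, mini_align_params):
        with pytest.raises(ValueError):
            ihrsr.run_ihrsr(noisy_stack.subset(np.array([], dtype=int)),
                            hg.HelicalSymmetry(-50.0, 15.5, 3))


class TestSortBySymmetry:
    def test_homogeneous_data_fills_central_bin(self, noisy_stack, card_volume,
                                                card_sym, mini_align_params):
        spec = ihrsr.SortSpec(center=card_sym, n_bins=9, d_twist=2.0, d_rise=1.5)
        assign, counts = ihrsr.sort_by_symmetry(
            noisy_stack, spec, card_volume, align_params=mini_align_params)
        assert counts.sum() == len(noisy_stack)
        assert np.argmax(counts) == 4  # center of the 3x3 grid

    def test_offcenter_data_lands_offcenter(self, card_tpl, card_volume, mini_align_params):
        off = hg.HelicalSymmetry(-53.6 - 2.0, 16.8, 3)  # center + one twist step
        stack = sg.simulate_segments(off, card_tpl, n_filaments=6, length=121,
                                     box=MINI_BOX, overlap=0.9, snr=0.5, seed=9,
                                     pixel=MINI_VOXEL, radius=32.0,
                                     tilt_jitter=4.0, inplane_jitter=3.0,
                                     shift_jitter_px=2.0)
        center = hg.HelicalSymmetry(-53.6, 16.8, 3)
        spec = ihrsr.SortSpec(center=center, n_bins=9, d_twist=2.0, d_rise=1.5)
        vol = sg.build_volume(off, card_tpl, radius=32.0, grid=MINI_BOX, voxel=MINI_VOXEL)
        assign, counts = ihrsr.sort_by_symmetry(stack, spec, vol,
                                                align_params=mini_align_params)
        grid3 = counts.reshape(3, 3)
        # modal twist row is the larger-magnitude one (|twist| + d_twist)
        assert np.argmax(grid3.sum(axis=1)) == 2

    def test_single_segment_single_bin(self, noisy_stack, card_volume, card_sym,
                                       mini_align_params):
        spec = ihrsr.SortSpec(center=card_sym, n_bins=1)
        assign, counts = ihrsr.sort_by_symmetry(
            noisy_stack.subset([0]), spec, card_volume, align_params=mini_align_params)
        assert counts.tolist() == [1]

    def test_invalid_bins_rejected(self, card_sym):
        with pytest.raises(ValueError):
            ihrsr.SortSpec(center=card_sym, n_bins=8)
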