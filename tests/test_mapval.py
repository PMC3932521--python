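"""Map validation: half splits, volume alignment, FSC, amplitude
correction, map-power consistency."""

import numpy as np
import pandas as pd
import pytest

from helixforge import heligeom as hg
from helixforge import synthgen as sg
from helixforge import ihrsr
from helixforge import mapval
from helixforge import layerlines as ll

from conftest import MINI_BOX, MINI_VOXEL


class TestSplitHalves:
    def test_filament_disjoint_balanced(self, noisy_stack):
        h1, h2 = mapval.split_halves(noisy_stack)
        f1 = set(h1.records["filament"])
        f2 = set(h2.records["filament"])
        assert f1.isdisjoint(f2)
        assert len(h1) + len(h2) == len(noisy_stack)
        assert abs(len(h1) - len(h2)) <= max(
            noisy_stack.records["filament"].value_counts())

    def test_single_filament_rejected(self, noisy_stack):
        one = noisy_stack.subset(
            np.nonzero(noisy_stack.records["filament"].to_numpy() == 0)[0])
        with pytest.raises(ValueError):
            mapval.split_halves(one)

    def test_segment_split_leaks_correlation(self, card_sym, card_tpl):
        """Half-maps from a filament-level split correlate less at high
        frequency than half-maps from an interleaved segment split of the
        same data: overlapping segments share structure phase."""
        stack = sg.simulate_segments(card_sym, card_tpl, n_filaments=6, length=121,
                                     box=MINI_BOX, overlap=0.9, snr=0.3, seed=21,
                                     pixel=MINI_VOXEL, radius=32.0,
                                     tilt_jitter=0.0, inplane_jitter=0.0,
                                     shift_jitter_px=0.0)

        def recon(sub):
            rec = sub.records
            al = pd.DataFrame(dict(
                azimuth=rec["azimuth"], tilt=rec["tilt"], inplane=rec["inplane"],
                xshift_px=rec["xshift_px"].round().astype(int),
                yshift_px=rec["zphase"] / sub.pixel, corr=1.0, flagged=False))
            return ihrsr.backproject(sub, al)

        hf1, hf2 = mapval.split_halves(stack)
        idx = np.arange(len(stack))
        hs1, hs2 = stack.subset(idx[::2]), stack.subset(idx[1::2])
        def hi_fsc(a, b):
            curve, _, _ = mapval.fsc_resolution(recon(a), recon(b))
            third = len(curve.fsc) // 3
            return float(np.mean(curve.fsc[-third:]))
        assert hi_fsc(hf1, hf2) < hi_fsc(hs1, hs2)


class TestAlignVolumes:
    def test_rotation_recovered(self, card_volume):
        from helixforge.ihrsr import _helical_op

        v2 = sg.DensityVolume(_helical_op(card_volume.grid, 30.0, 0.0), card_volume.voxel)
        out, v2a = mapval.align_volumes(card_volume, v2)
        # the volume is C3-symmetric: -30 is recovered modulo 120
        d = (out["rotation_deg"] + 30.0) % 120.0
        assert min(d, 120.0 - d) < 0.3
        cc = np.corrcoef(card_volume.grid[16:48].ravel(), v2a.grid[16:48].ravel())[0, 1]
        assert cc > 0.98

    def test_subpixel_shift_recovered(self, card_volume):
        from helixforge.ihrsr import _helical_op

        v2 = sg.DensityVolume(_helical_op(card_volume.grid, 0.0, 0.5), card_volume.voxel)
        out, _ = mapval.align_volumes(card_volume, v2)
        assert out["shift_px"] == pytest.approx(-0.5, abs=0.1)

    def test_self_alignment_identity(self, card_volume):
        out, _ = mapval.align_volumes(card_volume, card_volume)
        assert abs(out["rotation_deg"]) < 0.3
        assert abs(out["shift_px"]) < 0.1


class TestFSC:
    def test_self_fsc_is_one(self, card_volume):
        curve, res, flagged = mapval.fsc_resolution(card_volume, card_volume)
        assert np.allclose(curve.fsc, 1.0, atol=1e-9)
        assert flagged  # never crosses: resolution pinned at Nyquist
        assert res == pytest.approx(2 * card_volume.voxel)

    def test_negated_fsc_is_minus_one(self, card_volume):
        neg = sg.DensityVolume(-card_volume.grid, card_volume.voxel)
        curve, _, _ = mapval.fsc_resolution(card_volume, neg)
        assert np.allclose(curve.fsc, -1.0, atol=1e-9)

    def test_resolution_monotone_in_noise(self, card_volume):
        rng = np.random.default_rng(0)
        sigma0 = card_volume.grid.std()
        res = []
        for amp in [0.5, 1.0, 2.0, 4.0, 8.0]:
            n1 = rng.normal(0, amp * sigma0, card_volume.grid.shape)
            n2 = rng.normal(0, amp * sigma0, card_volume.grid.shape)
            v1 = sg.DensityVolume(card_volume.grid + n1, card_volume.voxel)
            v2 = sg.DensityVolume(card_volume.grid + n2, card_volume.voxel)
            _, r, _ = mapval.fsc_resolution(v1, v2)
            res.append(r)
        assert all(b >= a - 1e-9 for a, b in zip(res, res[1:]))

    def test_noise_free_half_recon_beats_3voxel(self, card_sym, card_tpl):
        stack = sg.simulate_segments(card_sym, card_tpl, n_filaments=8, length=121,
                                     box=MINI_BOX, overlap=0.9, noise_sigma=0.0,
                                     seed=31, pixel=MINI_VOXEL, radius=32.0,
                                     tilt_jitter=0.0, inplane_jitter=0.0,
                                     shift_jitter_px=0.0)
        h1, h2 = mapval.split_halves(stack)

        def recon(sub):
            rec = sub.records
            al = pd.DataFrame(dict(
                azimuth=rec["azimuth"], tilt=rec["tilt"], inplane=rec["inplane"],
                xshift_px=rec["xshift_px"],
                yshift_px=rec["zphase"] / sub.pixel, corr=1.0, flagged=False))
            return ihrsr.backproject(sub, al)

        _, res, _ = mapval.fsc_resolution(recon(h1), recon(h2))
        assert res < 3 * MINI_VOXEL


class TestAmplitudeCorrect:
    def test_bfactor_inverse_pair(self, card_volume):
        up = mapval.amplitude_correct(card_volume, "bfactor", B=-400.0, low_pass=None)
        back = mapval.amplitude_correct(up, "bfactor", B=400.0, low_pass=None)
        assert np.allclose(back.grid, card_volume.grid, atol=1e-8 * np.abs(card_volume.grid).max())

    def test_dc_conserved(self, card_volume):
        out = mapval.amplitude_correct(card_volume, "bfactor", B=-400.0, low_pass=None)
        assert out.grid.sum() == pytest.approx(card_volume.grid.sum(), rel=1e-9)

    def test_sharpening_boost_factor(self, card_volume):
        """B = -1100 A^2 multiplies the amplitude at frequency s by
        exp(1100 s^2 / 4) (checked below the low-pass edge)."""
        B = -1100.0
        out = mapval.amplitude_correct(card_volume, "bfactor", B=B, low_pass=9.6)
        from helixforge._fourier import cfftn

        F0, F1 = cfftn(card_volume.grid), cfftn(out.grid)
        N, c = card_volume.n, card_volume.n // 2
        s_test = 0.08  # 1/A, safely inside the low-pass edge at 1/9.6
        r_vox = s_test * N * card_volume.voxel
        z, y, x = np.indices(F0.shape)
        r = np.sqrt((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
        shell = np.abs(r - r_vox) < 0.5
        ratio = np.abs(F1[shell]).sum() / np.abs(F0[shell]).sum()
        s_vox = r[shell] / (N * card_volume.voxel)
        w = np.abs(F0[shell])
        expected = np.sum(w * np.exp(-B * s_vox ** 2 / 4.0)) / np.sum(w)
        assert ratio == pytest.approx(expected, rel=0.005)

    def test_constant_envelope_rescales(self, card_volume):
        ctf = sg.CTFParams(defocus_um=0.0, voltage_kv=300.0, cs_mm=0.0,
                           amplitude_contrast=1.0)  # CTF == -cos(0) == -1
        out = mapval.amplitude_correct(card_volume, "envelope", ctfs=[ctf],
                                       low_pass=None)
        assert np.allclose(out.grid, card_volume.grid, atol=1e-8)

    def test_zero_b_rejected(self, card_volume):
        with pytest.raises(ValueError):
            mapval.amplitude_correct(card_volume, "bfactor", B=0.0)


class TestMapPower:
    def test_layer_lines_match_raw_power(self, card_sym, card_tpl):
        """Axial layer-line positions from map projections coincide with
        the raw-data summed power within one Fourier pixel (the check run
        at the 128 px / 2.26 A condition where the meridional is clear)."""
        stack = sg.simulate_segments(card_sym, card_tpl, n_filaments=8, length=218,
                                     box=128, overlap=0.9, snr=0.5, seed=41,
                                     pixel=2.26, radius=32.0,
                                     tilt_jitter=0.0, inplane_jitter=0.0,
                                     shift_jitter_px=0.0)
        raw = ll.sum_power(stack)
        vol = sg.build_volume(card_sym, card_tpl, radius=32.0, grid=128, voxel=2.26)
        ref = ihrsr.impose_symmetry(vol, card_sym)
        mp = mapval.map_power_projections(ref, n_orientations=90)
        t_raw = ll.index_layer_lines(raw, filament_radius=45.0)
        t_map = ll.index_layer_lines(mp, filament_radius=45.0)
        mer_raw = t_raw[t_raw["bessel_n"] == 0]["z_star"].min()
        mer_map = t_map[t_map["bessel_n"] == 0]["z_star"].min()
        assert abs(mer_raw - mer_map) <= raw.freq_step

    def test_single_orientation_equals_projection_power(self, card_reference):
        from helixforge._fourier import cfft2

        mp = mapval.map_power_projections(card_reference, n_orientations=1)
        p = sg.project(card_reference, azimuth=0.0) / card_reference.voxel
        direct = np.abs(cfft2(p)) ** 2
        cc = np.corrcoef(mp.power.ravel(), direct.ravel())[0, 1]
        assert cc > 0.98

    def test_invariant_under_axial_rotation(self, card_reference):
        from helixforge.ihrsr import _helical_op

        rot = sg.DensityVolume(_helical_op(card_reference.grid, 40.0, 0.0),
                               card_reference.voxel)
        p1 = mapval.map_power_projections(card_reference, n_orientations=60)
        p2 = mapval.map_power_projections(rot, n_orientations=60)
        cc = np.corrcoef(p1.power.ravel(), p2.power.ravel())[0, 1]
        assert cc > 0.99
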