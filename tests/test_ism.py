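"""Reconstruction-pipeline tests: scan arithmetic, pinholing, reassignment
against a per-pixel oracle, deconvolution behaviour, end-to-end laws."""

import warnings

import numpy as np
import pytest

from mfism import (DeconvSpec, FocusLattice, PinholeSpec, ScanProtocol,
                   ScanStack, deconvolve, digital_pinhole, effective_sigma,
                   frame_count, num_scans, pixel_reassign, reconstruct,
                   sum_and_normalize, widefield_equivalent)
from mfism.ism import _pinhole_patch_weights
from mfism.metrics import GAUSS_FWHM
from mfism.synth import ImagingModel, SyntheticSample, simulate_scan
from mfism.workflows import measure_bead_fwhm


class TestScanArithmetic:
    @pytest.mark.parametrize("s,p,expect", [
        (3.0, 0.1725, 17),   # the instrument's stage step at 3 um pitch
        (1.0, 1.0, 1),
        (1.0, 0.3, 3),
        (3.0, 0.1875, 16),
    ])
    def test_num_scans_floor(self, s, p, expect):
        assert num_scans(s, p) == expect

    def test_num_scans_rejects_pitch_below_pixel(self):
        with pytest.raises(ValueError):
            num_scans(0.1, 0.2)

    @pytest.mark.parametrize("ns,expect", [(17, 289), (1, 1), (3, 9)])
    def test_frame_count(self, ns, expect):
        proto = ScanProtocol(pixel_size_um=1.0, pitch_um=float(ns))
        assert proto.ns_per_axis == ns
        assert frame_count(proto) == expect

    def test_offsets_row_major(self):
        proto = ScanProtocol(pixel_size_um=1.0, pitch_um=2.0)
        np.testing.assert_array_equal(proto.offsets_px(),
                                      [[0, 0], [0, 1], [1, 0], [1, 1]])

    def test_stack_frame_count_enforced(self):
        proto = ScanProtocol(pixel_size_um=1.0, pitch_um=3.0)
        lattice = FocusLattice.square(9, 3, 3.0)
        with pytest.raises(ValueError, match="NS"):
            ScanStack(frames=np.zeros((4, 9, 9)), protocol=proto,
                      lattice=lattice)


class TestEffectiveSigma:
    def test_symmetric_case(self):
        spec = DeconvSpec(sigma_ex_nm=200.0, sigma_em_nm=200.0, m=0.5)
        assert effective_sigma(spec) == pytest.approx(200.0 / np.sqrt(2))

    def test_computed_scaling_factor_equal_sigmas(self):
        spec = DeconvSpec(sigma_ex_nm=180.0, sigma_em_nm=180.0, m=None)
        assert spec.scaling_factor == pytest.approx(0.5)

    def test_reference_value(self):
        # 488/520 nm at NA 0.5: sigma_ex 211.4, sigma_em 225.2, m = 0.5
        sx = 0.51 * 488.0 / 0.5 / GAUSS_FWHM
        se = 0.51 * 520.0 / 0.5 / GAUSS_FWHM
        spec = DeconvSpec(sigma_ex_nm=sx, sigma_em_nm=se, m=0.5)
        expect = 0.5 * np.hypot(sx, se)  # closed form for m = 1/2
        assert effective_sigma(spec) == pytest.approx(expect, rel=1e-12)
        assert effective_sigma(spec) == pytest.approx(154.4, abs=0.5)


class TestDigitalPinhole:
    def test_constant_frame_returns_pinhole_weights(self):
        frame = np.full((41, 41), 2.0)
        spec = PinholeSpec(sigma_nm=770.0, patch_radius_um=1.5)
        patches, weights, skipped = digital_pinhole(
            frame, np.array([[20.0, 20.0]]), spec, pixel_size_um=0.1875)
        assert skipped == 0
        np.testing.assert_allclose(patches[0], 2.0 * weights[0], rtol=1e-12)
        expect = _pinhole_patch_weights(8, 770e-3 / 0.1875, 0.0, 0.0)
        np.testing.assert_allclose(weights[0], expect)

    def test_very_wide_pinhole_leaves_patch_unchanged(self, rng):
        frame = rng.uniform(1, 2, (41, 41))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = PinholeSpec(sigma_nm=1e7, patch_radius_um=1.5)
        patches, _, _ = digital_pinhole(frame, np.array([[20.0, 20.0]]),
                                        spec, pixel_size_um=0.1875)
        sub = frame[12:29, 12:29]
        np.testing.assert_allclose(patches[0], sub, rtol=1e-6)

    def test_border_positions_skipped(self):
        frame = np.ones((41, 41))
        spec = PinholeSpec(sigma_nm=770.0, patch_radius_um=1.5)
        _, _, skipped = digital_pinhole(
            frame, np.array([[2.0, 20.0], [20.0, 20.0]]), spec,
            pixel_size_um=0.1875)
        assert skipped == 1


class TestPixelReassign:
    def test_delta_patch_lands_at_doubled_coordinate(self):
        patch = np.zeros((9, 9))
        patch[4, 4] = 1.0  # delta at the focus centre
        w = np.ones((9, 9))
        acc, wmap = pixel_reassign([patch], [w], np.array([[10.0, 14.0]]),
                                   (64, 64))
        assert acc[20, 28] == pytest.approx(1.0)
        assert acc.sum() == pytest.approx(1.0)

    def test_matches_per_pixel_brute_force_oracle(self, rng):
        patches = [rng.uniform(size=(9, 9)) for _ in range(3)]
        weights = [rng.uniform(size=(9, 9)) for _ in range(3)]
        # fractional focus positions
        pos = np.array([[10.3, 12.7], [15.0, 9.5], [8.25, 8.0]])
        acc, wmap = pixel_reassign(patches, weights, pos, (64, 64))
        # oracle: loop every patch pixel, bilinear-splat at r+r0, c+c0
        acc_o = np.zeros((64, 64))
        wmap_o = np.zeros((64, 64))
        for patch, wpatch, (r, c) in zip(patches, weights, pos):
            rad = 4
            r0, c0 = np.floor(r), np.floor(c)
            for i in range(9):
                for j in range(9):
                    rr = r + (r0 - rad) + i
                    cc = c + (c0 - rad) + j
                    t0, l0 = int(np.floor(rr)), int(np.floor(cc))
                    fr, fc = rr - t0, cc - l0
                    for dt, wt in ((0, 1 - fr), (1, fr)):
                        for dl, wl in ((0, 1 - fc), (1, fc)):
                            acc_o[t0 + dt, l0 + dl] += wt * wl * patch[i, j]
                            wmap_o[t0 + dt, l0 + dl] += wt * wl * wpatch[i, j]
        np.testing.assert_allclose(acc, acc_o, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(wmap, wmap_o, rtol=1e-9, atol=1e-12)

    def test_position_patch_mismatch(self):
        with pytest.raises(ValueError):
            pixel_reassign([np.ones((9, 9))], [np.ones((9, 9))],
                           np.array([[1.0, 1.0], [2.0, 2.0]]), (32, 32))


class TestSumAndNormalize:
    def test_uniform_weights_plain_scaling(self, rng):
        acc = rng.uniform(size=(16, 16))
        out = sum_and_normalize(acc, np.full((16, 16), 4.0))
        np.testing.assert_allclose(out, acc / 4.0)

    def test_zero_weight_region_zeroed(self):
        acc = np.ones((8, 8))
        w = np.ones((8, 8))
        w[:4] = 0.0
        out = sum_and_normalize(acc, w)
        assert np.all(out[:4] == 0.0)
        np.testing.assert_allclose(out[4:], 1.0)


class TestDeconvolve:
    def test_delta_kernel_identity(self, rng):
        img = rng.uniform(size=(32, 32))
        np.testing.assert_array_equal(deconvolve(img, 0.0, 10), img)

    def test_monotone_sharpening_and_flux(self):
        y, x = np.mgrid[:64, :64]
        blob = np.exp(-((x - 32.0) ** 2 + (y - 32.0) ** 2) / (2 * 3.0 ** 2))
        out = deconvolve(blob, 3.0, 5)
        # flux-preserving updates
        assert out.sum() == pytest.approx(blob.sum(), rel=0.01)
        assert np.all(out >= 0)
        # FWHM strictly smaller afterwards
        prof_in = blob[32]
        prof_out = out[32]
        w_in = (prof_in > prof_in.max() / 2).sum()
        w_out = (prof_out > prof_out.max() / 2).sum()
        assert w_out < w_in

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            deconvolve(np.array([[1.0, np.nan]]), 1.0, 3)
        with pytest.raises(ValueError):
            deconvolve(np.array([[-1.0, 1.0]]), 1.0, 3)


def _bead_scan(sigma_nm=225.2, seed=1, budget=1e6, bead=(4.6, 4.4)):
    sample = SyntheticSample(field_size_um=9.0,
                             emitters=[[bead[0], bead[1], 1.0]])
    model = ImagingModel(sigma_ex_nm=sigma_nm, sigma_em_nm=sigma_nm,
                         camera_pixel_um=0.1875, photon_budget=budget,
                         read_noise=0.0)
    proto = ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)
    return simulate_scan(sample, model, proto, seed=seed), sample


class TestReconstruct:
    def test_empty_stack_gives_zero_result(self):
        proto = ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)
        lattice = FocusLattice.square(48, 16, 3.0)
        stack = ScanStack(frames=np.zeros((256, 48, 48)), protocol=proto,
                          lattice=lattice)
        res = reconstruct(stack)
        assert np.all(res.widefield == 0)
        assert np.all(res.reassigned_sum == 0)
        assert np.all(res.deconvolved == 0)

    def test_widefield_is_frame_sum(self, rng):
        proto = ScanProtocol(pixel_size_um=1.0, pitch_um=2.0)
        lattice = FocusLattice.square(8, 2, 2.0)
        frames = rng.uniform(size=(4, 8, 8))
        stack = ScanStack(frames=frames, protocol=proto, lattice=lattice)
        np.testing.assert_allclose(widefield_equivalent(stack),
                                   frames.sum(axis=0))

    def test_reassignment_linear_in_stack(self):
        stack1, _ = _bead_scan(seed=1, bead=(4.6, 4.4))
        stack2, _ = _bead_scan(seed=1, bead=(3.9, 5.1))
        a, b = 2.0, 0.5
        import dataclasses
        mixed = dataclasses.replace(
            stack1, frames=a * stack1.frames + b * stack2.frames)
        r_mix = reconstruct(mixed)
        r1 = reconstruct(stack1)
        r2 = reconstruct(stack2)
        # accumulation is linear; normalization divides by the same weights
        expect = a * r1.reassigned_sum + b * r2.reassigned_sum
        err = (np.linalg.norm(r_mix.reassigned_sum - expect)
               / np.linalg.norm(expect))
        assert err < 1e-9

    def test_detect_mode_runs_on_dense_sample(self):
        # a fluorescent baseline gives every focus a detectable spot,
        # the prerequisite for detection-driven pinhole placement
        sample = SyntheticSample(field_size_um=9.0,
                                 emitters=[[4.6, 4.4, 1.0]], flat_level=0.05)
        model = ImagingModel(sigma_ex_nm=225.2, sigma_em_nm=225.2,
                             camera_pixel_um=0.1875, photon_budget=1e5,
                             read_noise=0.0)
        proto = ScanProtocol(pixel_size_um=0.1875, pitch_um=3.0)
        stack = simulate_scan(sample, model, proto, seed=1)
        res = reconstruct(stack, mode="detect")
        assert res.provenance["n_refined"] >= 0.5 * res.provenance["n_pinholes"]
        dc = res.deconvolved
        r, c = np.unravel_index(np.argmax(dc), dc.shape)
        x, y = c * 0.09375, r * 0.09375
        assert abs(x - sample.emitters[0, 0]) < 0.15
        assert abs(y - sample.emitters[0, 1]) < 0.15

    def test_detect_mode_aborts_on_sparse_sample(self):
        stack, _ = _bead_scan()
        with pytest.raises(RuntimeError, match="too sparse"):
            reconstruct(stack, mode="detect")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sqrt2_reassignment_law(self, seed):
        """Matched-Gaussian scan: reassigned/widefield spot STD = 1/sqrt(2)."""
        stack, sample = _bead_scan(seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pin = PinholeSpec(sigma_nm=5000.0, patch_radius_um=1.5)
        res = reconstruct(stack, pinhole=pin)
        wf = measure_bead_fwhm(res.widefield, 0.1875, sample.emitters[:, :2])
        rs = measure_bead_fwhm(res.reassigned_sum, 0.09375,
                               sample.emitters[:, :2])
        ratio = rs[0] / wf[0]
        assert ratio == pytest.approx(1.0 / np.sqrt(2), rel=0.05)
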