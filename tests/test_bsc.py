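"""Block tiling, power spectra, BSC estimation and the Gaussian-model fit."""

import numpy as np
import pytest

import qusbead as q
from qusbead.bsc import BlockSpectrum


class _Geom:
    """Minimal geometry carrier for tiling tests."""

    def __init__(self, dz_mm, pitch_mm):
        self.dz_mm = dz_mm
        self.pitch_mm = pitch_mm


class TestTiling:
    def test_9mm_square_75pct_overlap_gives_81_blocks(self):
        # stride 0.75 mm -> 9 positions per axis on a 9 mm extent
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        n_ax = int(round(9.0 / geom.dz_mm))
        n_lat = int(round(9.0 / geom.pitch_mm))
        mask = np.ones((n_ax, n_lat), dtype=np.uint8)
        grid = q.tile_blocks(mask, geom, block_size_mm=3.0, overlap_fraction=0.75)
        assert grid.n_rows == 9 and grid.n_cols == 9
        assert len(grid.blocks) == 81
        assert grid.excluded == []

    def test_zero_overlap_gives_disjoint_3x3(self):
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        mask = np.ones((int(round(9.0 / geom.dz_mm)), 30), dtype=np.uint8)
        grid = q.tile_blocks(mask, geom, block_size_mm=3.0, overlap_fraction=0.0)
        assert len(grid.blocks) == 9
        for a in grid.blocks:
            for b in grid.blocks:
                if a.block_id != b.block_id:
                    assert not a.intersects((b.r0, b.r1, b.c0, b.c1))

    def test_block_count_matches_stride_formula_on_rectangles(self):
        geom = _Geom(dz_mm=0.02, pitch_mm=0.25)
        for ext_mm in (6.0, 7.5, 12.0):
            mask = np.ones((int(round(ext_mm / geom.dz_mm)),
                            int(round(ext_mm / geom.pitch_mm))), dtype=np.uint8)
            grid = q.tile_blocks(mask, geom, block_size_mm=3.0,
                                 overlap_fraction=0.75)
            per_axis = int(np.floor((ext_mm - 3.0) / 0.75 + 1e-9)) + 1
            assert len(grid.blocks) == per_axis ** 2

    def test_bead_zone_excluded_with_reason(self):
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        n_ax = int(round(9.0 / geom.dz_mm))
        mask = np.ones((n_ax, 30), dtype=np.uint8)
        center = (n_ax // 2, 15)
        zone = (center[0] - 10, center[0] + 10, center[1] - 2, center[1] + 2)
        grid = q.tile_blocks(mask, geom, bead_zone=zone)
        assert grid.excluded_reasons.get("bead", 0) > 0
        for blk in grid.blocks:
            assert not blk.intersects(zone)
        for blk, reason in grid.excluded:
            if reason == "bead":
                assert blk.intersects(zone)

    def test_low_coverage_blocks_dropped(self):
        # elliptical mask: corner blocks of the bounding box fall below the
        # 75 % in-mask coverage rule
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        mask = q.ellipse_mask((600, 40), geom.dz_mm, geom.pitch_mm,
                              (5.5, 5.5), (5.0, 5.0))
        grid = q.tile_blocks(mask, geom)
        assert grid.excluded_reasons.get("coverage", 0) > 0
        for blk in grid.blocks:
            sub = mask[blk.r0:blk.r1, blk.c0:blk.c1]
            assert sub.mean() >= 0.75

    def test_mask_smaller_than_block_warns_and_returns_empty(self):
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        mask = np.zeros((500, 30), dtype=np.uint8)
        mask[10:40, 2:5] = 1  # ~0.6 x 0.9 mm
        with pytest.warns(UserWarning):
            grid = q.tile_blocks(mask, geom)
        assert grid.blocks == []

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            q.tile_blocks(np.zeros((10, 10)), _Geom(0.02, 0.3))


class TestBlockSpectrum:
    def _frame(self, samples, fs=40e6):
        return q.RFFrame(samples=samples, fs=fs, fc=6.6e6, pitch_mm=0.3)

    def test_sinusoid_peaks_at_its_frequency(self):
        fs, f0 = 40e6, 5e6
        t = np.arange(512) / fs
        rf = self._frame(np.tile(np.sin(2 * np.pi * f0 * t)[:, None], (1, 4)))
        blk = q.Block(0, 0, 0, 0, 512, 0, 4)
        spec = q.block_power_spectrum(rf, blk)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(f0, rel=0.02)
        assert spec.n_lines_averaged == 4

    def test_gain_scales_power_quadratically(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((256, 6))
        blk = q.Block(0, 0, 0, 0, 256, 0, 6)
        w1 = q.block_power_spectrum(self._frame(x), blk)
        w3 = q.block_power_spectrum(self._frame(3.0 * x), blk)
        np.testing.assert_allclose(w3.power, 9.0 * w1.power, rtol=1e-9)

    def test_white_noise_expected_spectrum_flat(self):
        # Monte-Carlo average over seeds; Hann window leaves a flat shape
        rng = np.random.default_rng(1)
        acc = None
        blk = q.Block(0, 0, 0, 0, 256, 0, 8)
        for _ in range(60):
            w = q.block_power_spectrum(self._frame(rng.standard_normal((256, 8))), blk)
            acc = w.power if acc is None else acc + w.power
        acc /= 60
        interior = acc[10:-10]
        assert interior.std() / interior.mean() < 0.15

    def test_short_gate_rejected(self):
        rf = self._frame(np.ones((16, 4)))
        with pytest.raises(ValueError):
            q.block_power_spectrum(rf, q.Block(0, 0, 0, 0, 3, 0, 4))

    def test_block_outside_frame_rejected(self):
        rf = self._frame(np.ones((64, 4)))
        with pytest.raises(ValueError):
            q.block_power_spectrum(rf, q.Block(0, 0, 0, 32, 128, 0, 4))


class TestBeadSpectrum:
    def test_single_line_equals_its_periodogram(self, phantom_frame, bmode,
                                                bsf_template):
        _, frame, gt = phantom_frame
        det = q.locate_bead(bmode, bsf_template, mask=gt.mask)
        w_narrow = q.bead_power_spectrum(frame, det, gate_mm=4.0,
                                         lateral_extent_mm=frame.pitch_mm * 1.01)
        assert w_narrow.n_lines_averaged <= 3
        assert np.all(w_narrow.power >= 0)

    def test_duplicated_lines_leave_average_unchanged(self):
        rng = np.random.default_rng(3)
        line = rng.standard_normal(256)
        f1 = q.RFFrame(samples=np.tile(line[:, None], (1, 2)), fs=40e6, fc=6.6e6,
                       pitch_mm=0.3)
        f2 = q.RFFrame(samples=np.tile(line[:, None], (1, 6)), fs=40e6, fc=6.6e6,
                       pitch_mm=0.3)
        det = q.BeadDetection(0, 128, 1, 0, 0, 1.0, False, False)
        det2 = q.BeadDetection(0, 128, 3, 0, 0, 1.0, False, False)
        w1 = q.bead_power_spectrum(f1, det, gate_mm=2.0, lateral_extent_mm=10.0)
        w2 = q.bead_power_spectrum(f2, det2, gate_mm=2.0, lateral_extent_mm=1.0)
        np.testing.assert_allclose(w1.power, w2.power, rtol=1e-9)

    def test_clean_bead_spectrum_proportional_to_pulse_power(self, pulse_spec):
        # speckle-free bead -> line-averaged spectrum tracks |P(f)|^2 within
        # the band (reverberation comb removed by gating the main echo only)
        spec = q.PhantomSpec(scatterer_density=0.0, tissue_attenuation_db_cm_mhz=0.0,
                             bead=q.BeadSpec(reverb_count=0), seed=0)
        frame, gt = q.synthesize_rf(spec, pulse_spec)
        r, c = frame.mm_to_px(*gt.bead_position_mm)
        det = q.BeadDetection(0, r, c, *gt.bead_position_mm, 1.0, False, False)
        w = q.bead_power_spectrum(frame, det, gate_mm=3.0, nfft=2048)
        pulse = q.make_pulse(pulse_spec)
        pf2 = np.abs(np.fft.rfft(pulse.samples, 2048)) ** 2
        band = (w.frequencies > 4.5e6) & (w.frequencies < 8.7e6)
        ratio = w.power[band] / pf2[band]
        assert ratio.std() / ratio.mean() < 0.05

    def test_detection_outside_frame_rejected(self, phantom_frame):
        _, frame, _ = phantom_frame
        det = q.BeadDetection(0, 10 ** 6, 0, 0, 0, 1.0, False, False)
        with pytest.raises(ValueError):
            q.bead_power_spectrum(frame, det, gate_mm=3.0)


def _curve_from_model(d_um, eac, f_lo=4e6, f_hi=10e6, n=80, c=1540.0):
    freqs = np.linspace(f_lo, f_hi, n)
    return q.BSCCurve(frequencies=freqs,
                      sigma=q.gaussian_model_bsc(freqs, d_um, eac, c))


class TestEstimateBSC:
    def _ref(self, freqs, w_bead, sigma_bead):
        w = BlockSpectrum(frequencies=freqs, power=w_bead, block_id=-1,
                          n_lines_averaged=1)
        return q.make_bead_reference(w, (freqs, sigma_bead))

    def test_ratio_identity_w_equals_wbead(self):
        freqs = np.linspace(3e6, 10e6, 64)
        w_bead = np.exp(-((freqs - 6.6e6) / 2e6) ** 2)
        sigma_bead = 0.3 * np.ones_like(freqs)
        ref = self._ref(freqs, w_bead, sigma_bead)
        w = BlockSpectrum(frequencies=freqs, power=w_bead.copy(), block_id=0,
                          n_lines_averaged=1)
        curve = q.estimate_bsc(w, ref)
        np.testing.assert_array_equal(curve.sigma, ref.sigma_bead[ref.band])

    def test_common_gain_cancels_exactly(self):
        freqs = np.linspace(3e6, 10e6, 64)
        rng = np.random.default_rng(0)
        w_bead = np.exp(-((freqs - 6.6e6) / 2e6) ** 2) * (1 + 0.1 * rng.random(64))
        w_samp = w_bead * (0.5 + rng.random(64))
        sigma_bead = 1.0 + rng.random(64)
        ref = self._ref(freqs, w_bead, sigma_bead)
        base = q.estimate_bsc(BlockSpectrum(freqs, w_samp, 0, 1), ref)
        g = 7.3
        ref_g = self._ref(freqs, g * w_bead, sigma_bead)
        gained = q.estimate_bsc(BlockSpectrum(freqs, g * w_samp, 0, 1), ref_g)
        np.testing.assert_allclose(base.sigma, gained.sigma, rtol=1e-14)

    def test_common_frequency_dependent_loss_cancels_exactly(self):
        freqs = np.linspace(3e6, 10e6, 64)
        rng = np.random.default_rng(1)
        w_bead = np.exp(-((freqs - 6.6e6) / 2e6) ** 2) * (1 + 0.1 * rng.random(64))
        w_samp = w_bead * (0.5 + rng.random(64))
        sigma_bead = np.ones_like(freqs)
        loss = np.exp(-freqs / 4e6)  # arbitrary common loss L(f)
        band = (4e6, 9e6)  # fixed band so both estimates share a grid
        w0 = BlockSpectrum(frequencies=freqs, power=w_bead, block_id=-1,
                           n_lines_averaged=1)
        wL = BlockSpectrum(frequencies=freqs, power=loss * w_bead, block_id=-1,
                           n_lines_averaged=1)
        ref0 = q.make_bead_reference(w0, (freqs, sigma_bead), band_hz=band)
        refL = q.make_bead_reference(wL, (freqs, sigma_bead), band_hz=band)
        s0 = q.estimate_bsc(BlockSpectrum(freqs, w_samp, 0, 1), ref0)
        sL = q.estimate_bsc(BlockSpectrum(freqs, loss * w_samp, 0, 1), refL)
        np.testing.assert_allclose(s0.sigma, sL.sigma, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        freqs = np.linspace(3e6, 10e6, 64)
        ref = self._ref(freqs, np.ones(64), np.ones(64))
        w = BlockSpectrum(np.linspace(3e6, 10e6, 32), np.ones(32), 0, 1)
        with pytest.raises(ValueError):
            q.estimate_bsc(w, ref)


class TestGaussianFit:
    def test_noiseless_roundtrip_machine_precision(self):
        fit = q.fit_gaussian_model(_curve_from_model(25.0, 10.0))
        assert fit.valid
        assert fit.d_um == pytest.approx(25.0, rel=1e-6)
        assert fit.eac == pytest.approx(10.0, rel=1e-6)
        assert fit.residual < 1e-20

    @pytest.mark.parametrize("d_um,eac", [(10.0, 1.0), (40.0, 0.03), (80.0, 250.0)])
    def test_roundtrip_across_parameter_range(self, d_um, eac):
        fit = q.fit_gaussian_model(_curve_from_model(d_um, eac))
        assert fit.valid
        assert fit.d_um == pytest.approx(d_um, rel=1e-6)
        assert fit.eac == pytest.approx(eac, rel=1e-6)

    def test_esd_is_3_11_times_d(self):
        fit = q.fit_gaussian_model(_curve_from_model(1.0, 5.0))
        assert fit.esd_um == pytest.approx(3.11 * fit.d_um, rel=1e-12)
        assert fit.esd_um == pytest.approx(3.11, rel=1e-6)

    def test_flat_k4_curve_is_invalid_sentinel(self):
        freqs = np.linspace(4e6, 10e6, 50)
        k = 2 * np.pi * freqs / 1540.0
        curve = q.BSCCurve(frequencies=freqs, sigma=k ** 4)  # s = 0
        fit = q.fit_gaussian_model(curve, d_bounds_um=(1.0, 500.0))
        assert not fit.valid
        assert fit.d_um == 1.0  # sentinel at the configured lower bound
        assert np.isnan(fit.eac)

    def test_out_of_bounds_d_invalid(self):
        fit = q.fit_gaussian_model(_curve_from_model(40.0, 1.0),
                                   d_bounds_um=(1.0, 30.0))
        assert not fit.valid

    def test_too_few_points_rejected(self):
        freqs = np.linspace(4e6, 10e6, 4)
        with pytest.raises(ValueError):
            q.fit_gaussian_model(q.BSCCurve(freqs, np.ones(4)))

    def test_nonpositive_sigma_rejected(self):
        freqs = np.linspace(4e6, 10e6, 20)
        sigma = np.ones(20)
        sigma[3] = 0.0
        with pytest.raises(ValueError):
            q.fit_gaussian_model(q.BSCCurve(freqs, sigma))


class TestParamMap:
    def _grid_with(self, n):
        geom = _Geom(dz_mm=0.01925, pitch_mm=0.3)
        mask = np.ones((int(round(6.0 / geom.dz_mm)), 20), dtype=np.uint8)
        grid = q.tile_blocks(mask, geom, overlap_fraction=0.0)
        assert len(grid.blocks) == n
        return grid

    def test_uniform_valid_fits(self):
        grid = self._grid_with(4)
        fit = q.fit_gaussian_model(_curve_from_model(30.0, 2.0))
        pmap = q.build_param_map(grid, [fit] * 4)
        assert pmap.esd_mean == pytest.approx(fit.esd_um)
        assert pmap.esd_std == 0.0
        assert pmap.n_valid == 4

    def test_invalid_fit_excluded_from_summary(self):
        grid = self._grid_with(4)
        good = q.fit_gaussian_model(_curve_from_model(30.0, 2.0))
        freqs = np.linspace(4e6, 10e6, 30)
        k = 2 * np.pi * freqs / 1540.0
        bad = q.fit_gaussian_model(q.BSCCurve(freqs, k ** 4))
        pmap = q.build_param_map(grid, [good, good, good, bad])
        assert pmap.n_valid == 3
        assert pmap.esd_mean == pytest.approx(good.esd_um)
        assert np.isnan(pmap.esd_um).sum() == 1

    def test_zero_valid_fits_flagged(self):
        grid = self._grid_with(4)
        freqs = np.linspace(4e6, 10e6, 30)
        k = 2 * np.pi * freqs / 1540.0
        bad = q.fit_gaussian_model(q.BSCCurve(freqs, k ** 4))
        with pytest.warns(UserWarning):
            pmap = q.build_param_map(grid, [bad] * 4)
        assert not pmap.summary_defined

    def test_fit_count_mismatch_rejected(self):
        grid = self._grid_with(4)
        with pytest.raises(ValueError):
            q.build_param_map(grid, [])


class TestRelativeError:
    def test_values(self):
        assert q.relative_error(10.0, 10.0) == 0.0
        assert q.relative_error(11.0, 10.0) == pytest.approx(0.10)
        assert q.relative_error(9.0, 10.0) == pytest.approx(0.10)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            q.relative_error(1.0, 0.0)
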