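"""4D decoding, EPI extraction, and scattering purification."""

import numpy as np
import pytest

import epilocate as ep
from epilocate.decode import (brightest_epi_indices, central_subaperture,
                              extract_epi_pair, max_projection_epi, retile)
from epilocate.dictionary import fit_epi_slope

from conftest import DEPTHS, render_bead


class TestDecode4D:
    def test_round_trip_and_conservation(self, cfg, sweep_renders,
                                         ideal_calib):
        raw = sweep_renders[16.0]
        lf = ep.decode_4d(raw, ideal_calib)
        assert lf.total_intensity == pytest.approx(raw.image.sum())
        assert np.array_equal(retile(lf), raw.image)

    def test_overlapping_windows_rejected(self, cfg, sweep_renders):
        calib = ep.CalibrationResult.ideal(cfg)
        calib.pitch_px = cfg.n_i - 2        # pitch below the window size
        with pytest.raises(ValueError):
            ep.decode_4d(sweep_renders[0.0], calib)

    def test_infocus_bead_lights_central_lenslet(self, cfg, sweep_renders,
                                                 ideal_calib):
        lf = ep.decode_4d(sweep_renders[0.0], ideal_calib)
        sub = central_subaperture(lf)
        K, L = cfg.lenslet_count
        assert np.unravel_index(np.argmax(sub), sub.shape) \
            == (K // 2, L // 2)

    def test_subaperture_is_a_slice(self, sweep_renders, ideal_calib):
        lf = ep.decode_4d(sweep_renders[8.0], ideal_calib)
        assert np.array_equal(ep.subaperture(lf, 3, 5), lf.data[3, 5])
        # summing all sub-apertures re-counts every micro-image pixel once
        total = sum(ep.subaperture(lf, i, j).sum()
                    for i in range(lf.n_views[0])
                    for j in range(lf.n_views[1]))
        assert total == pytest.approx(lf.total_intensity)


class TestEPIs:
    def test_infocus_epi_line_is_vertical(self, sweep_renders, ideal_calib):
        lf = ep.decode_4d(sweep_renders[0.0], ideal_calib)
        epi_h, _ = extract_epi_pair(lf)
        assert abs(fit_epi_slope(epi_h)) < 0.05

    def test_slope_magnitude_grows_with_depth(self, sweep_renders,
                                              ideal_calib):
        slopes = {}
        for z in (8.0, 20.0):
            lf = ep.decode_4d(sweep_renders[z], ideal_calib)
            epi_h, _ = extract_epi_pair(lf)
            slopes[z] = abs(fit_epi_slope(epi_h))
        assert slopes[20.0] > slopes[8.0]

    def test_slope_monotone_over_depth_sweep(self, sweep_renders,
                                             ideal_calib):
        mags = []
        for z in DEPTHS[1:]:
            lf = ep.decode_4d(sweep_renders[float(z)], ideal_calib)
            epi_h, _ = extract_epi_pair(lf)
            mags.append(abs(fit_epi_slope(epi_h)))
        assert np.all(np.diff(mags) > 0)

    def test_lateral_shift_moves_line_one_sample(self, cfg, field_cache,
                                                 sweep_renders, ideal_calib):
        # one lenslet pitch in object space = one spatial EPI sample
        delta = cfg.lenslet_pitch_um / cfg.magnification
        lf0 = ep.decode_4d(sweep_renders[16.0], ideal_calib)
        raw1 = render_bead(cfg, field_cache, delta, 0.0, 16.0)
        lf1 = ep.decode_4d(raw1, ideal_calib)
        n_i, n_j = lf0.n_views
        K, L = lf0.n_lenslets
        # x-shift shows in the vertical (j-l) EPI through the centre row
        e0 = ep.extract_epi(lf0, "vertical", n_i // 2, K // 2).data
        e1 = ep.extract_epi(lf1, "vertical", n_i // 2, K // 2).data
        assert np.allclose(e1[:, :-1], e0[:, 1:], rtol=1e-3,
                           atol=1e-6 * e0.max())
        assert abs(fit_epi_slope(e1) - fit_epi_slope(e0)) < 0.05

    def test_index_bounds_checked(self, sweep_renders, ideal_calib):
        lf = ep.decode_4d(sweep_renders[0.0], ideal_calib)
        with pytest.raises(IndexError):
            ep.extract_epi(lf, "horizontal", 99, 0)


class TestBackgroundRemoval:
    def test_rank_one_input_gives_zero_foreground(self):
        rng = np.random.default_rng(0)
        u = rng.random(25)
        v = rng.random(9)
        stack = np.outer(u, v).T.reshape(9, 5, 5)
        fg, model = ep.remove_background(stack)
        assert np.abs(fg).max() < 1e-12 * model.sigma_max
        assert model.matrix.shape == (25, 9)
        assert np.linalg.norm(model.u_max) == pytest.approx(1.0)
        assert np.linalg.norm(model.v_max) == pytest.approx(1.0)

    def test_bright_spot_recovered_over_background(self):
        # rank-one subtraction absorbs whatever part of the foreground
        # projects onto the background's singular subspace, so faithful
        # spot recovery needs the spot nearly orthogonal to it: here the
        # background is vignetted onto the early views and the spot
        # appears only in late views where the background is negligible
        rng = np.random.default_rng(1)
        u = 1.0 + rng.random(900)               # 30x30 spatial profile
        v = np.exp(-((np.arange(12) - 2.0) / 1.5) ** 2)
        bg = np.outer(u, v).T.reshape(12, 30, 30)
        spot = np.zeros_like(bg)
        for j in (9, 10, 11):
            spot[j, 15, 10 + j] = 0.5 * bg.max()
        fg, _ = ep.remove_background(bg + spot)
        err = np.linalg.norm(fg - spot) / np.linalg.norm(spot)
        assert err < 0.05

    def test_energy_splits_orthogonally(self):
        rng = np.random.default_rng(2)
        stack = rng.random((6, 8, 8))
        fg, model = ep.remove_background(stack)
        A = stack.reshape(6, -1).T
        B = model.matrix
        F = fg.reshape(6, -1).T
        assert np.linalg.norm(A) ** 2 == pytest.approx(
            np.linalg.norm(B) ** 2 + np.linalg.norm(F) ** 2)
        assert abs(np.sum(B * F)) < 1e-8 * np.linalg.norm(A) ** 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ep.remove_background(np.zeros((4, 5, 5)))
        with pytest.raises(ValueError):
            ep.remove_background(np.ones((1, 5, 5)))


class TestMaxProjection:
    def test_constant_epi(self):
        rows, cols = max_projection_epi(np.full((4, 7), 3.5))
        assert np.all(rows == 3.5) and np.all(cols == 3.5)
        assert rows.shape == (4,) and cols.shape == (7,)

    def test_single_pixel(self):
        e = np.zeros((5, 6))
        e[2, 4] = 7.0
        rows, cols = max_projection_epi(e)
        assert rows[2] == 7.0 and np.all(np.delete(rows, 2) == 0)
        assert cols[4] == 7.0 and np.all(np.delete(cols, 4) == 0)

    def test_dimmer_pixels_do_not_change_profiles(self):
        e = np.zeros((5, 6))
        e[2, 4] = 7.0
        r0, c0 = max_projection_epi(e)
        e2 = e.copy()
        e2[2, 1] = 3.0
        e2[0, 4] = 2.0
        r1, c1 = max_projection_epi(e2)
        assert r1[2] == r0[2] and c1[4] == c0[4]


def test_brightest_epi_indices_track_bead(cfg, field_cache, ideal_calib):
    # a bead two lenslets off-axis moves the EPI extraction point with it
    delta = 2 * cfg.lenslet_pitch_um / cfg.magnification
    raw = render_bead(cfg, field_cache, delta, -delta, 0.0)
    lf = ep.decode_4d(raw, ideal_calib)
    K, L = lf.n_lenslets
    k0, l0 = brightest_epi_indices(lf)
    assert (k0, l0) == (K // 2 + 2, L // 2 - 2)
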