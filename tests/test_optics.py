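"""Wave-optics forward model: diffraction, propagation, linearity."""

import numpy as np
import pytest
import scipy.signal

import epilocate as ep
from epilocate.optics import (ComplexField, PointSource, _DepthFieldCache,
                              debye_wavefront, field_grid, fresnel_propagate,
                              mla_mask, psf, render_lightfield)
from epilocate.dictionary import discretize_ball

from conftest import OVERSAMPLE


def test_config_invariants():
    with pytest.raises(ValueError):
        ep.OpticalConfig(0.52, 25, 1.5, 125, 1250, (19, 19), 125 / 19,
                         medium_refractive_index=1.33)   # NA > n
    with pytest.raises(ValueError):
        ep.OpticalConfig(-0.52, 25, 1.0, 125, 1250, (19, 19), 125 / 19)
    with pytest.raises(ValueError):
        # pitch not an integer number of pixels within one pixel
        ep.OpticalConfig(0.52, 25, 1.0, 125, 1250, (19, 19), 4.0)


class TestDebyeWavefront:
    def test_onaxis_field_radially_symmetric(self, tiny_cfg):
        g = field_grid(tiny_cfg, 2)
        u = np.abs(debye_wavefront(PointSource(0, 0, 0), tiny_cfg, g).data)
        assert np.allclose(u, u[::-1, :], rtol=1e-10)
        assert np.allclose(u, u[:, ::-1], rtol=1e-10)
        assert np.allclose(u, u.T, rtol=1e-10)

    def test_lateral_shift_is_pure_image_translation(self, tiny_cfg):
        # one lenslet pitch in object space shifts the (inverted) image
        # field by exactly -d, which is grid-exact
        g = field_grid(tiny_cfg, 2)
        d_px = int(tiny_cfg.lenslet_pitch_um / g.spacing_um)
        u0 = debye_wavefront(PointSource(0, 0, 0), tiny_cfg, g).data
        delta = tiny_cfg.lenslet_pitch_um / tiny_cfg.magnification
        u1 = debye_wavefront(PointSource(delta, 0, 0), tiny_cfg, g).data
        shifted = np.roll(u0, -d_px, axis=1)
        core = (slice(d_px, -d_px),) * 2
        assert np.allclose(u1[core], shifted[core], atol=1e-10)

    def test_low_na_profile_reproduces_airy_pattern(self):
        # independent oracle: closed-form Airy amplitude 2 J1(v)/v
        from scipy.special import j1
        cfg = ep.OpticalConfig(0.52, 25, 0.2, 125, 1250, (19, 19), 125 / 19)
        from epilocate.optics import debye_radial_profile
        r, prof = debye_radial_profile(0.0, cfg, 8.0, 0.005)
        v = 2 * np.pi / cfg.wavelength_um * cfg.numerical_aperture * r
        airy = np.ones_like(v)
        airy[1:] = 2 * j1(v[1:]) / v[1:]
        a = np.abs(prof) / np.abs(prof[0])
        assert np.allclose(a, np.abs(airy), atol=5e-3)

    def test_central_lobe_radius_near_airy_at_full_na(self, cfg):
        g = field_grid(cfg, OVERSAMPLE)
        u = debye_wavefront(PointSource(0, 0, 0), cfg, g)
        prof = np.abs(u.data[u.data.shape[0] // 2])
        c = int(np.argmax(prof))
        mins = scipy.signal.argrelmin(prof)[0]
        first_zero = (mins[mins > c][0] - c) * g.spacing_um
        airy = 0.61 * cfg.wavelength_um * cfg.magnification \
            / cfg.numerical_aperture
        assert abs(first_zero - airy) <= g.spacing_um


class TestMLAMask:
    def test_periodicity_with_pitch(self, tiny_cfg):
        g = field_grid(tiny_cfg, 2)
        m = mla_mask(tiny_cfg, g).data
        period = int(tiny_cfg.lenslet_pitch_um / g.spacing_um)
        assert np.allclose(m[:, :-period], m[:, period:], atol=1e-12)
        assert np.allclose(m[:-period, :], m[period:, :], atol=1e-12)

    def test_phase_only_and_zero_phase_at_centres(self, tiny_cfg):
        # oversample 1 puts lenslet centres exactly on grid points
        g = field_grid(tiny_cfg, 1)
        m = mla_mask(tiny_cfg, g)
        assert np.allclose(np.abs(m.data), 1.0, atol=1e-12)
        y, _ = g.coords
        d = tiny_cfg.lenslet_pitch_um
        yl = np.mod(y + d / 2, d) - d / 2
        rows = np.flatnonzero(yl == 0.0)
        assert rows.size == tiny_cfg.lenslet_count[0]
        ph = np.angle(m.data[np.ix_(rows, rows)])
        assert np.all(np.abs(ph) < 1e-12)


class TestFresnel:
    def test_zero_distance_is_identity(self, tiny_cfg):
        rng = np.random.default_rng(0)
        f = ComplexField(rng.normal(size=(64, 64))
                         + 1j * rng.normal(size=(64, 64)), 2.0)
        out = fresnel_propagate(f, 0.0, tiny_cfg)
        assert np.array_equal(out.data, f.data)

    def test_energy_conservation(self, tiny_cfg):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(128, 128)) + 1j * rng.normal(size=(128, 128))
        f = ComplexField(data, 2.0)
        out = fresnel_propagate(f, 450.0, tiny_cfg)
        assert abs(out.energy - f.energy) / f.energy < 1e-8

    def test_gaussian_beam_waist_matches_closed_form(self, tiny_cfg):
        lam, w0, z = tiny_cfg.wavelength_um, 20.0, 1800.0
        n = 256
        c = (np.arange(n) - (n - 1) / 2) * 2.0
        r2 = np.add.outer(c ** 2, c ** 2)
        f = ComplexField(np.exp(-r2 / w0 ** 2).astype(complex), 2.0)
        out = fresnel_propagate(f, z, tiny_cfg)
        inten = np.abs(out.data) ** 2
        # w(z)/2 is the second-moment radius of the intensity per axis
        var = (inten.sum(axis=0) * c ** 2).sum() / inten.sum()
        w_meas = 2 * np.sqrt(var)
        zr = np.pi * w0 ** 2 / lam
        w_true = w0 * np.sqrt(1 + (z / zr) ** 2)
        assert abs(w_meas - w_true) / w_true < 0.01


class TestPSF:
    def test_onaxis_psf_nonnegative_and_symmetric(self, tiny_cfg):
        h = psf(PointSource(0, 0, 0), tiny_cfg, oversample=2)
        assert h.shape == tiny_cfg.sensor_shape
        assert np.all(h >= 0)
        assert np.allclose(h, h[::-1, :], rtol=1e-4, atol=1e-9 * h.max())
        assert np.allclose(h, h.T, rtol=1e-4, atol=1e-9 * h.max())
        # concentrated under the central lenslet
        n = tiny_cfg.n_i
        K = tiny_cfg.lenslet_count[0]
        blocks = h.reshape(K, n, K, n).sum(axis=(1, 3))
        assert np.unravel_index(np.argmax(blocks), blocks.shape) \
            == (K // 2, K // 2)

    def test_footprint_radius_monotone_in_depth(self, cfg, field_cache):
        radii = []
        for z in (0.0, 8.0, 16.0, 32.0, 48.0):
            h = psf(PointSource(0, 0, z), cfg, _cache=field_cache)
            yy, xx = np.indices(h.shape)
            c = (h.shape[0] - 1) / 2
            r2 = (yy - c) ** 2 + (xx - c) ** 2
            radii.append(np.sqrt((h * r2).sum() / h.sum()))
        assert np.all(np.diff(radii) > 0)

    def test_lateral_equivariance_at_one_lenslet(self, cfg, field_cache):
        delta = cfg.lenslet_pitch_um / cfg.magnification
        h0 = psf(PointSource(0, 0, 16.0), cfg, _cache=field_cache)
        h1 = psf(PointSource(delta, 0, 16.0), cfg, _cache=field_cache)
        n = cfg.n_i
        shifted = np.roll(h0, -n, axis=1)
        core = (slice(None), slice(n, -n))
        assert np.allclose(h1[core], shifted[core],
                           atol=1e-6 * h0.max())


class TestRenderLightfield:
    def test_single_point_equals_psf(self, tiny_cfg):
        p = PointSource(1.0, -2.0, 6.0)
        vol = ep.VolumeSource(np.array([[p.x, p.y, p.z]]), np.ones(1))
        img = render_lightfield(vol, tiny_cfg, oversample=2).image
        assert np.allclose(img, psf(p, tiny_cfg, oversample=2), rtol=1e-10)

    def test_linear_in_emitter_intensities(self, tiny_cfg):
        pts = np.array([[0.0, 0.0, 4.0], [2.0, -1.0, 8.0]])
        v1 = ep.VolumeSource(pts[:1], np.array([1.0]))
        v2 = ep.VolumeSource(pts[1:], np.array([2.0]))
        v12 = ep.VolumeSource(pts, np.array([1.0, 2.0]))
        cache = _DepthFieldCache(tiny_cfg, field_grid(tiny_cfg, 2))
        i1 = render_lightfield(v1, tiny_cfg, 2, _cache=cache).image
        i2 = render_lightfield(v2, tiny_cfg, 2, _cache=cache).image
        i12 = render_lightfield(v12, tiny_cfg, 2, _cache=cache).image
        assert np.allclose(i1 + i2, i12, rtol=1e-12)
        v_scaled = ep.VolumeSource(pts, 3.0 * np.array([1.0, 2.0]))
        i_scaled = render_lightfield(v_scaled, tiny_cfg, 2,
                                     _cache=cache).image
        assert np.allclose(i_scaled, 3.0 * i12, rtol=1e-12)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            ep.VolumeSource(np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(ValueError):
            ep.VolumeSource(np.zeros((2, 3)), np.zeros(2))  # zero intensity
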