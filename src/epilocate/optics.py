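"""Wave-optics forward model of a microlens-based light-field microscope.

The sensor-plane point-spread function of a point source at
``p = (p1, p2, p3)`` (object space, um; ``p3 = 0`` is the native focal
plane, positive is deeper) is computed as

    h(x, p) = IFFT{ FFT{ U_i(x, p) * Phi(x) } * G(f) },     |h|^2 recorded,

where ``U_i`` is the field at the native image plane (the inverted,
M-times stretched Debye wavefront of the objective), ``Phi`` is the
phase-only transmittance mask of the MLA, and ``G`` is the paraxial
(Fresnel) transfer function for the MLA-to-sensor distance ``f_ML``.
Extended sources are incoherent: their images superpose in intensity,

    f(x) = sum_p |h(x, p)|^2 g(p).

Fields are simulated on a grid that oversamples the sensor by an integer
factor and are integrated (binned) down to sensor pixels at the end, which
keeps the lenslet quadratic phase adequately sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy.special import j0

from .config import OpticalConfig

__all__ = [
    "PointSource", "VolumeSource", "ComplexField", "RawLightField",
    "FieldGrid", "field_grid", "debye_wavefront", "mla_mask",
    "fresnel_propagate", "psf", "render_lightfield", "SamplingError",
]


class SamplingError(ValueError):
    """Raised when a simulation grid is too coarse for the configured NA."""


@dataclass(frozen=True)
class PointSource:
    """Ideal emitter at object-space position (x, y, z) in um."""
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("point source coordinates must be finite")

    @property
    def lateral(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class VolumeSource:
    """Discretized extended emitter: grid points with intensities g >= 0."""
    points: np.ndarray          # (n, 3) object-space um
    intensities: np.ndarray     # (n,)
    center: PointSource | None = None
    diameter_um: float = 0.0
    grid_step_um: float = 0.0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.points.shape[0] != self.intensities.shape[0]:
            raise ValueError("points and intensities must align")
        if np.any(self.intensities < 0):
            raise ValueError("emitter intensities must be non-negative")
        if self.points.shape[0] == 0 or self.intensities.sum() <= 0:
            raise ValueError("volume source must carry positive total intensity")


@dataclass
class ComplexField:
    """2D complex amplitude on a square grid centred on the optical axis."""
    data: np.ndarray
    spacing_um: float

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.data.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing_um
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing_um
        return y, x

    @property
    def energy(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class RawLightField:
    """A 2D sensor image plus optional calibration metadata."""
    image: np.ndarray
    config: OpticalConfig | None = None
    rotation_deg: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FieldGrid:
    """Oversampled simulation grid aligned with the sensor pixel grid."""
    shape: tuple[int, int]
    spacing_um: float
    oversample: int

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing_um
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing_um
        return y, x


def field_grid(cfg: OpticalConfig, oversample: int = 4) -> FieldGrid:
    """Simulation grid covering the full sensor, ``oversample`` sub-pixels
    per sensor pixel in each axis."""
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    rows, cols = cfg.sensor_shape
    spacing = cfg.sensor_pixel_pitch_um / oversample
    return FieldGrid((rows * oversample, cols * oversample), spacing, oversample)


def _check_sampling(cfg: OpticalConfig, spacing_um: float) -> None:
    # Nyquist spacing for the *intensity* at the image plane is
    # lambda*M/(4 NA); the field amplitude itself is band-limited to half
    # that, so only spacings beyond lambda*M/(2 NA) alias the field.
    nyq_intensity = cfg.wavelength_um * cfg.magnification / (4 * cfg.numerical_aperture)
    if spacing_um > 2 * nyq_intensity:
        raise SamplingError(
            f"grid spacing {spacing_um:.3g} um aliases the NA-limited field "
            f"(limit {2 * nyq_intensity:.3g} um)")
    if spacing_um > nyq_intensity * 1.05:
        warnings.warn(
            f"grid spacing {spacing_um:.3g} um under-samples the intensity "
            f"(Nyquist {nyq_intensity:.3g} um); increase oversampling for "
            "photometric accuracy", RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Debye wavefront
# ---------------------------------------------------------------------------

_N_THETA = 200          # Gauss-Legendre nodes over the aperture half-angle
_R_STEP_UM = 0.05       # object-space radial table step
_MAX_DEPTH_UM = 200.0   # defocus beyond this is not validated


def debye_radial_profile(z_um: float, cfg: OpticalConfig,
                         r_max_um: float, r_step_um: float = _R_STEP_UM
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Radial profile U_o(r; z) of the scalar Debye integral.

    Circular aperture of half-angle ``alpha = asin(NA/n)`` with sine-
    condition apodization sqrt(cos theta) and defocus phase
    ``exp(i k n z (1 - cos theta))``.  Returns (r_um, complex profile).
    """
    if abs(z_um) > _MAX_DEPTH_UM:
        raise ValueError(f"axial position {z_um} um outside the simulated "
                         f"range (+-{_MAX_DEPTH_UM} um)")
    n = cfg.medium_refractive_index
    alpha = np.arcsin(cfg.numerical_aperture / n)
    k = 2 * np.pi / cfg.wavelength_um
    nodes, weights = np.polynomial.legendre.leggauss(_N_THETA)
    theta = 0.5 * alpha * (nodes + 1.0)
    w = 0.5 * alpha * weights
    st, ct = np.sin(theta), np.cos(theta)
    defocus = np.exp(1j * k * n * z_um * (1.0 - ct))
    r = np.arange(0.0, r_max_um + r_step_um, r_step_um)
    # J0 kernel: (n_r, n_theta)
    bessel = j0(k * n * np.outer(r, st))
    prof = bessel @ (np.sqrt(ct) * st * defocus * w)
    return r, prof


def debye_wavefront(p: PointSource, cfg: OpticalConfig,
                    grid: FieldGrid) -> ComplexField:
    """Field U_i at the native image plane for a point source at ``p``.

    U_i(x, p) = U_o(-x/M, p): the objective inverts and stretches the
    object-plane wavefront, so a source at lateral position (p1, p2)
    appears centred at image coordinate -M (p1, p2).
    """
    _check_sampling(cfg, grid.spacing_um)
    M = cfg.magnification
    y, x = grid.coords
    # object-space radius of each image grid point relative to the source
    ro_y = y / M + p.y   # |-x/M - p| = |x + M p| / M
    ro_x = x / M + p.x
    r2d = np.hypot.outer(ro_y, ro_x)
    r_tab, prof = debye_radial_profile(p.z, cfg, float(r2d.max()) + 2 * _R_STEP_UM)
    data = np.interp(r2d.ravel(), r_tab, prof.real) \
        + 1j * np.interp(r2d.ravel(), r_tab, prof.imag)
    return ComplexField(data.reshape(r2d.shape), grid.spacing_um)


# ---------------------------------------------------------------------------
# MLA mask and Fresnel propagation
# ---------------------------------------------------------------------------

def mla_mask(cfg: OpticalConfig, grid: FieldGrid) -> ComplexField:
    """Phase-only MLA transmittance: a thin-lens quadratic phase
    ``exp(-i pi ||x_local||^2 / (lambda f_ML))`` tiled with pitch d."""
    d = cfg.lenslet_pitch_um
    rows, cols = grid.shape
    expected = (cfg.sensor_shape[0] * grid.oversample,
                cfg.sensor_shape[1] * grid.oversample)
    if (rows, cols) != expected:
        raise ValueError("grid does not cover an integer number of lenslets")
    y, x = grid.coords
    yl = np.mod(y + d / 2.0, d) - d / 2.0
    xl = np.mod(x + d / 2.0, d) - d / 2.0
    phase = -np.pi * (np.add.outer(yl ** 2, xl ** 2)) \
        / (cfg.wavelength_um * cfg.mla_focal_length_um)
    return ComplexField(np.exp(1j * phase), grid.spacing_um)


def fresnel_transfer(shape: tuple[int, int], spacing_um: float,
                     distance_um: float, wavelength_um: float) -> np.ndarray:
    """Paraxial transfer function exp(-i pi lambda z ||f||^2) (unit
    modulus, hence energy conserving)."""
    fy = np.fft.fftfreq(shape[0], d=spacing_um)
    fx = np.fft.fftfreq(shape[1], d=spacing_um)
    f2 = np.add.outer(fy ** 2, fx ** 2)
    return np.exp(-1j * np.pi * wavelength_um * distance_um * f2)


def fresnel_propagate(fld: ComplexField, distance_um: float,
                      cfg: OpticalConfig) -> ComplexField:
    """Propagate a band-limited field by ``distance_um`` (paraxial)."""
    if distance_um < 0:
        raise ValueError("propagation distance must be >= 0")
    if distance_um == 0:
        return ComplexField(fld.data.copy(), fld.spacing_um)
    n = max(fld.data.shape)
    # quadratic phase of G under-sampled beyond z ~ N * dx^2 / lambda
    z_alias = n * fld.spacing_um ** 2 / cfg.wavelength_um
    if distance_um > z_alias:
        warnings.warn(
            f"Fresnel transfer function under-sampled at z={distance_um:g} um "
            f"(aliasing-free up to ~{z_alias:g} um)", RuntimeWarning)
    G = fresnel_transfer(fld.data.shape, fld.spacing_um, distance_um,
                         cfg.wavelength_um)
    out = np.fft.ifft2(np.fft.fft2(fld.data) * G)
    return ComplexField(out, fld.spacing_um)


def _bin_to_sensor(intensity: np.ndarray, oversample: int) -> np.ndarray:
    """Integrate an oversampled intensity grid down to sensor pixels."""
    if oversample == 1:
        return intensity
    rows, cols = intensity.shape
    return intensity.reshape(rows // oversample, oversample,
                             cols // oversample, oversample).sum(axis=(1, 3))


# ---------------------------------------------------------------------------
# PSF and extended-source rendering
# ---------------------------------------------------------------------------

class _DepthFieldCache:
    """Per-depth cache of the on-axis image-plane field in Fourier form.

    The Debye field is strictly band-limited by the NA, so a laterally
    shifted source is obtained exactly by a Fourier phase ramp applied to
    the cached on-axis spectrum.
    """

    def __init__(self, cfg: OpticalConfig, grid: FieldGrid,
                 dtype=np.complex64):
        self.cfg = cfg
        self.grid = grid
        self.dtype = dtype
        self.mask = mla_mask(cfg, grid).data.astype(dtype)
        self.G = fresnel_transfer(grid.shape, grid.spacing_um,
                                  cfg.mla_focal_length_um,
                                  cfg.wavelength_um).astype(dtype)
        self._fy = np.fft.fftfreq(grid.shape[0], d=grid.spacing_um)
        self._fx = np.fft.fftfreq(grid.shape[1], d=grid.spacing_um)
        self._spectra: dict[float, np.ndarray] = {}

    def _spectrum(self, z_um: float) -> np.ndarray:
        key = round(float(z_um), 9)
        if key not in self._spectra:
            u0 = debye_wavefront(PointSource(0.0, 0.0, z_um), self.cfg,
                                 self.grid)
            self._spectra[key] = sfft.fft2(u0.data.astype(self.dtype))
        return self._spectra[key]

    def sensor_intensity(self, p: PointSource) -> np.ndarray:
        """|h|^2 on the oversampled grid for a single point source."""
        spec = self._spectrum(p.z)
        M = self.cfg.magnification
        # image-plane centre of the field is at -M * (p.x, p.y)
        cy, cx = -M * p.y, -M * p.x
        ramp = np.exp(np.outer(-2j * np.pi * self._fy * cy,
                               np.ones_like(self._fx))
                      + np.outer(np.ones_like(self._fy),
                                 -2j * np.pi * self._fx * cx)).astype(self.dtype)
        u_i = sfft.ifft2(spec * ramp)
        h = sfft.ifft2(sfft.fft2(u_i * self.mask) * self.G)
        return (h.real ** 2 + h.imag ** 2).astype(np.float64)


def psf(p: PointSource, cfg: OpticalConfig, oversample: int = 4,
        _cache: _DepthFieldCache | None = None) -> np.ndarray:
    """Sensor-pixel intensity PSF |h(x, p)|^2 (shape ``cfg.sensor_shape``).

    Deterministic for fixed inputs.  The field is simulated on an
    ``oversample``-times finer grid and integrated to sensor pixels.
    """
    cache = _cache or _DepthFieldCache(cfg, field_grid(cfg, oversample))
    return _bin_to_sensor(cache.sensor_intensity(p), cache.grid.oversample)


def render_lightfield(vol: VolumeSource, cfg: OpticalConfig,
                      oversample: int = 4,
                      _cache: _DepthFieldCache | None = None) -> RawLightField:
    """Raw light-field image of an extended source: the incoherent
    superposition sum_p |h(x,p)|^2 g(p) over the volume's grid points.

    Exactly linear in the emitter intensities ``g``.
    """
    cache = _cache or _DepthFieldCache(cfg, field_grid(cfg, oversample))
    acc = np.zeros(cache.grid.shape, dtype=np.float64)
    for (x, y, z), g in zip(vol.points, vol.intensities):
        if g == 0.0:
            continue
        acc += g * cache.sensor_intensity(PointSource(x, y, z))
    return RawLightField(_bin_to_sensor(acc, cache.grid.oversample), cfg)
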