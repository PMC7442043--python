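"""Optical configuration of the light-field microscope.

All physical quantities are in micrometres (um) unless stated otherwise.
The sensor sits at the back focal plane of the microlens array (MLA), so
each lenslet forms a micro-image of ``pixels_per_lenslet`` pixels and the
lenslet pitch equals an integer number of sensor pixels after calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["OpticalConfig", "default_config", "load_config", "save_config"]


@dataclass(frozen=True)
class OpticalConfig:
    """Physical constants of a microlens-based light-field microscope.

    Parameters
    ----------
    wavelength_um : float
        Emission wavelength (vacuum).
    magnification : float
        Lateral magnification M of the objective + tube-lens 4-f relay.
    numerical_aperture : float
        Objective NA; must not exceed the medium refractive index.
    lenslet_pitch_um : float
        MLA pitch d measured at the sensor plane.
    mla_focal_length_um : float
        Focal length of the lenslets (sensor at the MLA back focal plane).
    pixels_per_lenslet : tuple of int
        (N_i, N_j) sensor pixels behind each lenslet.
    sensor_pixel_pitch_um : float
        Physical pixel pitch of the camera.
    medium_refractive_index : float
        Refractive index of the immersion/sample medium.
    lenslet_count : tuple of int
        (K, L) lenslets simulated / decoded.
    """

    wavelength_um: float
    magnification: float
    numerical_aperture: float
    lenslet_pitch_um: float
    mla_focal_length_um: float
    pixels_per_lenslet: tuple[int, int]
    sensor_pixel_pitch_um: float
    medium_refractive_index: float = 1.33
    lenslet_count: tuple[int, int] = (15, 15)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels_per_lenslet",
                           tuple(int(v) for v in _pair(self.pixels_per_lenslet)))
        object.__setattr__(self, "lenslet_count",
                           tuple(int(v) for v in _pair(self.lenslet_count)))
        for name in ("wavelength_um", "magnification", "numerical_aperture",
                     "lenslet_pitch_um", "mla_focal_length_um",
                     "sensor_pixel_pitch_um", "medium_refractive_index"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(v <= 0 for v in self.pixels_per_lenslet + self.lenslet_count):
            raise ValueError("pixel and lenslet counts must be positive")
        if self.numerical_aperture > self.medium_refractive_index:
            raise ValueError("NA cannot exceed the medium refractive index")
        n_i = self.pixels_per_lenslet[0]
        if abs(n_i * self.sensor_pixel_pitch_um - self.lenslet_pitch_um) \
                > self.sensor_pixel_pitch_um:
            raise ValueError(
                "lenslet pitch must equal pixels_per_lenslet * pixel pitch "
                "within one pixel")

    # -- derived geometry ------------------------------------------------
    @property
    def n_i(self) -> int:
        return self.pixels_per_lenslet[0]

    @property
    def n_j(self) -> int:
        return self.pixels_per_lenslet[1]

    @property
    def n_lenslets(self) -> tuple[int, int]:
        return self.lenslet_count

    @property
    def sensor_shape(self) -> tuple[int, int]:
        K, L = self.lenslet_count
        return (K * self.n_i, L * self.n_j)

    @property
    def image_na(self) -> float:
        """Image-side numerical aperture NA / M."""
        return self.numerical_aperture / self.magnification

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pixels_per_lenslet"] = list(self.pixels_per_lenslet)
        d["lenslet_count"] = list(self.lenslet_count)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


def default_config(lenslet_count: int | tuple[int, int] = (15, 15)) -> OpticalConfig:
    """25x / NA 1.0 water-immersion system with a 125 um, f/10 MLA.

    19 pixels per lenslet (pixel pitch d / 19) and a green emission
    wavelength of 0.52 um.  ``lenslet_count`` controls the simulated field
    of view; the default 15 x 15 keeps simulations fast while leaving room
    for the defocus footprint of sources up to ~48 um deep.
    """
    return OpticalConfig(
        wavelength_um=0.52,
        magnification=25.0,
        numerical_aperture=1.0,
        lenslet_pitch_um=125.0,
        mla_focal_length_um=1250.0,
        pixels_per_lenslet=(19, 19),
        sensor_pixel_pitch_um=125.0 / 19.0,
        medium_refractive_index=1.33,
        lenslet_count=_pair(lenslet_count),
    )


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (int, float)):
        return (int(v), int(v))
    a, b = v
    return (int(a), int(b))


def load_config(path: str | Path) -> OpticalConfig:
    with open(path) as fh:
        return OpticalConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: OpticalConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
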