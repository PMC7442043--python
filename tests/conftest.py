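"""Shared fixtures: the desk-scale optical preset and cached simulations.

Simulation parameters used throughout the suite (the "desk-scale
preset"): 15 x 15 lenslets, 19 x 19 pixels per lenslet, 2x field
oversampling and a 2 um ball discretization step — small enough that the
whole suite runs in a few minutes on one CPU while preserving every
qualitative feature of the full-scale system (depth-dependent epipolar
slope, lenslet truncation at depth, photometric linearity).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import epilocate as ep
from epilocate.calibration import CalibrationResult
from epilocate.optics import _DepthFieldCache, field_grid

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*under-samples.*")

DEPTHS = np.arange(0.0, 48.1, 4.0)     # dictionary depth grid (um)
OVERSAMPLE = 2
GRID_STEP = 2.0                        # ball discretization step (um)
BALL_DIAMETER = 10.0


@pytest.fixture(scope="session")
def cfg():
    return ep.default_config()


@pytest.fixture(scope="session")
def tiny_cfg():
    """Minimal 5x5-lenslet system for cheap pure-optics tests."""
    return ep.OpticalConfig(
        wavelength_um=0.52, magnification=25.0, numerical_aperture=1.0,
        lenslet_pitch_um=45.0, mla_focal_length_um=450.0,
        pixels_per_lenslet=(9, 9), sensor_pixel_pitch_um=5.0,
        medium_refractive_index=1.33, lenslet_count=(5, 5))


@pytest.fixture(scope="session")
def field_cache(cfg):
    """Shared per-depth field cache so repeated renders are cheap."""
    return _DepthFieldCache(cfg, field_grid(cfg, OVERSAMPLE))


@pytest.fixture(scope="session")
def sweep_renders(cfg, field_cache):
    """One on-axis 10 um ball render per dictionary depth."""
    return ep.render_depth_sweep(cfg, DEPTHS, diameter_um=BALL_DIAMETER,
                                 grid_step_um=GRID_STEP,
                                 oversample=OVERSAMPLE)


@pytest.fixture(scope="session")
def dict_pair(cfg, sweep_renders):
    return ep.build_dictionary_pair(cfg, DEPTHS, diameter_um=BALL_DIAMETER,
                                    grid_step_um=GRID_STEP,
                                    oversample=OVERSAMPLE,
                                    renders=sweep_renders)


@pytest.fixture(scope="session")
def ideal_calib(cfg):
    return CalibrationResult.ideal(cfg)


def render_bead(cfg, cache, x, y, z):
    vol = ep.discretize_ball(ep.PointSource(x, y, z), BALL_DIAMETER,
                             GRID_STEP)
    return ep.render_lightfield(vol, cfg, OVERSAMPLE, _cache=cache)


@pytest.fixture(scope="session")
def bead_set(cfg, field_cache):
    """20 single-bead frames at seeded random on-grid depths and random
    lateral positions within +-1.5 lenslets of the axis."""
    rng = np.random.default_rng(20260921)
    frames = []
    for _ in range(20):
        z = float(rng.choice(DEPTHS))
        x, y = (float(v) for v in rng.uniform(-7.5, 7.5, 2))
        frames.append((render_bead(cfg, field_cache, x, y, z), (x, y, z)))
    return frames


def localize_frame(raw, calib, dict_h, dict_v, S=1):
    lf = ep.decode_4d(raw, calib)
    epi_h, epi_v = ep.extract_epi_pair(lf)
    return ep.localize(epi_h, epi_v, dict_h, dict_v, S=S)


@pytest.fixture(scope="session")
def bead_predictions(bead_set, ideal_calib, dict_pair):
    """Noiseless localization of every bead in ``bead_set``."""
    dh, dv = dict_pair
    preds, truths = [], []
    for raw, (x, y, z) in bead_set:
        res = localize_frame(raw, ideal_calib, dh, dv)
        preds.append(res.positions[0])
        truths.append([x, y, z])
    return np.asarray(preds), np.asarray(truths)
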