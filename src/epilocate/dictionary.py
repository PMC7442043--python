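"""Depth-aware EPI dictionary synthesized with the wave-optics model.

Each atom is the EPI of a ball-shaped volume (default 10 um diameter — the
scale of a neuronal soma) placed on the optical axis at one depth of a
sweep.  The slope of the epipolar line grows with depth, so selecting the
best-matching atom during sparse coding reads the depth straight out of
the lookup table.  Atoms are cropped to a common spatial window centred on
the EPI centre column and normalized to unit l2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .calibration import CalibrationResult
from .config import OpticalConfig
from .decode import EPI, decode_4d, extract_epi
from .optics import (PointSource, VolumeSource, _DepthFieldCache,
                     field_grid, render_lightfield)

__all__ = [
    "EPIDictionary", "discretize_ball", "build_dictionary",
    "build_dictionary_pair", "render_depth_sweep", "transverse_sampling",
    "fit_epi_slope",
]


@dataclass
class EPIDictionary:
    """Bank of unit-norm EPI atoms with a depth lookup table.

    ``anchor_col`` is the spatial index within an atom that corresponds to
    the EPI centre column of the generating (on-axis) source; coefficient-
    map peak positions are translated to lateral offsets relative to it.
    """
    atoms: np.ndarray            # (M_atoms, n_ang, n_sp)
    depths_um: np.ndarray        # (M_atoms,) strictly increasing
    orientation: str
    anchor_col: int
    config: OpticalConfig
    ball_diameter_um: float

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.atoms.shape[0] != self.depths_um.size:
            raise ValueError("one depth per atom required")
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def depth_step_um(self) -> float:
        if self.depths_um.size < 2:
            return 0.0
        return float(np.min(np.diff(self.depths_um)))

    def depth_lookup(self, m: int) -> float:
        """Depth (um) associated with atom index ``m`` (0-based)."""
        if not 0 <= m < self.n_atoms:
            raise IndexError(f"atom index {m} out of range")
        return float(self.depths_um[m])

    def gram(self) -> np.ndarray:
        flat = self.atoms.reshape(self.n_atoms, -1)
        return flat @ flat.T

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("atoms", data=self.atoms)
            fh.create_dataset("depths", data=self.depths_um)
            fh.attrs["orientation"] = self.orientation
            fh.attrs["anchor_col"] = self.anchor_col
            fh.attrs["ball_diameter_um"] = self.ball_diameter_um
            import json
            fh.attrs["optical_config"] = json.dumps(self.config.to_dict())

    @classmethod
    def load(cls, path: str | Path) -> "EPIDictionary":
        import json
        with h5py.File(path, "r") as fh:
            return cls(
                atoms=fh["atoms"][()],
                depths_um=fh["depths"][()],
                orientation=str(fh.attrs["orientation"]),
                anchor_col=int(fh.attrs["anchor_col"]),
                config=OpticalConfig.from_dict(
                    json.loads(fh.attrs["optical_config"])),
                ball_diameter_um=float(fh.attrs["ball_diameter_um"]),
            )


def discretize_ball(center: PointSource, diameter_um: float,
                    grid_step_um: float) -> VolumeSource:
    """Uniform-intensity lattice discretization of a ball.

    Grid points within ``diameter/2`` of the centre carry unit intensity.
    A zero-diameter ball degenerates to the centre point alone.
    """
    if diameter_um < 0 or grid_step_um <= 0:
        raise ValueError("diameter must be >= 0 and grid step > 0")
    if diameter_um == 0:
        return VolumeSource(np.array([[center.x, center.y, center.z]]),
                            np.ones(1), center, 0.0, grid_step_um)
    if grid_step_um > diameter_um / 4.0:
        raise ValueError(
            f"grid step {grid_step_um} um too coarse for a {diameter_um} um "
            "ball (need step <= diameter/4)")
    r = diameter_um / 2.0
    m = int(np.floor(r / grid_step_um))
    off = np.arange(-m, m + 1) * grid_step_um
    gx, gy, gz = np.meshgrid(off, off, off, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) <= r ** 2 + 1e-12]
    pts = pts + np.array([center.x, center.y, center.z])
    return VolumeSource(pts, np.ones(len(pts)), center, diameter_um,
                        grid_step_um)


def render_depth_sweep(cfg: OpticalConfig, depths_um, diameter_um: float = 10.0,
                       grid_step_um: float = 1.0, oversample: int = 4,
                       center_xy: tuple[float, float] = (0.0, 0.0)):
    """Render one raw light-field per depth for a ball on the optical axis
    (or at ``center_xy``).  Returns ``{depth: RawLightField}``.  One field
    cache is shared across the sweep."""
    depths = np.asarray(list(depths_um), dtype=float)
    if depths.size == 0 or np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be non-empty and strictly increasing")
    cache = _DepthFieldCache(cfg, field_grid(cfg, oversample))
    out = {}
    for z in depths:
        vol = discretize_ball(PointSource(center_xy[0], center_xy[1], z),
                              diameter_um, grid_step_um)
        out[float(z)] = render_lightfield(vol, cfg, oversample, _cache=cache)
    return out


def _sweep_epis(cfg: OpticalConfig, renders: dict) -> dict:
    """Central-row/column EPIs of each rendered sweep image."""
    calib = CalibrationResult.ideal(cfg)
    K, L = cfg.lenslet_count
    n_i, n_j = cfg.pixels_per_lenslet
    epis = {}
    for z, raw in renders.items():
        lf = decode_4d(raw, calib)
        epi_h = extract_epi(lf, "horizontal", n_j // 2, L // 2)
        epi_v = extract_epi(lf, "vertical", n_i // 2, K // 2)
        epis[z] = (epi_h, epi_v)
    return epis


def _atom_window(epis_spatial: list[np.ndarray], width_cap: int) -> tuple[int, int]:
    """Common spatial crop: bounding box of the deepest epipolar line plus
    a 2-sample margin, centred on the EPI centre column."""
    deepest = epis_spatial[-1]
    col_energy = (deepest ** 2).sum(axis=0)
    above = np.flatnonzero(col_energy > 1e-6 * col_energy.max())
    lo, hi = int(above[0]), int(above[-1])
    lo, hi = max(lo - 2, 0), min(hi + 2, width_cap - 1)
    return lo, hi


def build_dictionary_pair(cfg: OpticalConfig, depths_um,
                          diameter_um: float = 10.0,
                          grid_step_um: float = 1.0,
                          oversample: int = 4,
                          renders: dict | None = None
                          ) -> tuple[EPIDictionary, EPIDictionary]:
    """Build horizontal and vertical dictionaries from one depth sweep.

    ``renders`` may carry a precomputed ``render_depth_sweep`` result to
    avoid re-simulating.
    """
    depths = np.asarray(list(depths_um), dtype=float)
    if renders is None:
        renders = render_depth_sweep(cfg, depths, diameter_um, grid_step_um,
                                     oversample)
    epis = _sweep_epis(cfg, renders)
    out = []
    for which in (0, 1):   # horizontal, vertical
        raw_epis = [epis[float(z)][which].data for z in depths]
        lo, hi = _atom_window(raw_epis, raw_epis[-1].shape[1])
        atoms = []
        for z, e in zip(depths, raw_epis):
            a = e[:, lo:hi + 1]
            nrm = np.linalg.norm(a)
            if nrm == 0:
                raise ValueError(f"zero-energy atom at depth {z} um")
            atoms.append(a / nrm)
        center_col = raw_epis[-1].shape[1] // 2
        out.append(EPIDictionary(
            np.stack(atoms), depths,
            "horizontal" if which == 0 else "vertical",
            anchor_col=center_col - lo, config=cfg,
            ball_diameter_um=diameter_um))
    return out[0], out[1]


def build_dictionary(cfg: OpticalConfig, depths_um,
                     diameter_um: float = 10.0,
                     orientation: str = "horizontal",
                     grid_step_um: float = 1.0,
                     oversample: int = 4) -> EPIDictionary:
    """Depth-aware EPI dictionary for one orientation."""
    dh, dv = build_dictionary_pair(cfg, depths_um, diameter_um,
                                   grid_step_um, oversample)
    return dh if orientation == "horizontal" else dv


def transverse_sampling(cfg: OpticalConfig, super_resolved: bool = False
                        ) -> float:
    """Object-space transverse sampling step (um).

    The native lateral resolution limit of light-field microscopy is one
    lenslet, d/M; deconvolution-style super-resolved grids subdivide each
    lenslet into its N_i angular samples, d/(M N_i).
    """
    d, M = cfg.lenslet_pitch_um, cfg.magnification
    if super_resolved:
        return d / (M * cfg.n_i)
    return d / M


def fit_epi_slope(epi: EPI | np.ndarray, border_px: int = 1) -> float:
    """Slope of the epipolar line in spatial samples per angular sample.

    Per angular row, the line position is the intensity centroid of a
    +-2-sample window around the row peak (sub-sample, robust to lines
    truncated by the field of view).  Rows whose peak touches the spatial
    border, or with negligible energy, are excluded; the remaining
    positions are fit by least squares weighted by row peak intensity.
    """
    data = epi.data if isinstance(epi, EPI) else np.asarray(epi, dtype=float)
    n_ang, n_sp = data.shape
    rows, pos, wts = [], [], []
    vmax = data.max()
    for i in range(n_ang):
        row = data[i]
        p = int(np.argmax(row))
        if row[p] < 0.05 * vmax:
            continue
        if p < border_px or p >= n_sp - border_px:
            continue
        lo, hi = max(p - 2, 0), min(p + 3, n_sp)
        seg = row[lo:hi] - row[lo:hi].min()
        if seg.sum() == 0:
            centroid = float(p)
        else:
            centroid = float((seg * np.arange(lo, hi)).sum() / seg.sum())
        rows.append(i)
        pos.append(centroid)
        wts.append(row[p])
    if len(rows) < 3:
        raise ValueError("too few usable rows to fit an EPI slope")
    rows, pos, wts = map(np.asarray, (rows, pos, wts))
    W = np.sqrt(wts)
    A = np.column_stack([rows, np.ones_like(rows)]) * W[:, None]
    coef, *_ = np.linalg.lstsq(A, pos * W, rcond=None)
    return float(coef[0])
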