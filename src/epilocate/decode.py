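"""Decode a calibrated raw light-field into 4D form and extract EPIs.

Axis semantics of the 4D light-field ``I4D(i, j, k, l)``:

* ``(i, j)`` — angular indices: pixel row/column within a micro-image;
* ``(k, l)`` — spatial indices: lenslet row/column on the MLA grid.

A sub-aperture image fixes ``(i, j)``; an epipolar-plane image (EPI)
fixes one angular and one spatial index.  Following the convention used
throughout this package,

* horizontal EPI: ``I4D(:, j0, :, l0)`` with axes (i, k);
* vertical EPI:   ``I4D(i0, :, k0, :)`` with axes (j, l);

axis 0 of an EPI is always angular, axis 1 spatial.  A source at depth z
traces a tilted line whose slope grows with z; an in-focus source gives a
vertical (zero-slope) line.

Scattering backgrounds are removed by a rank-one SVD factorization of the
matrix whose columns are the vectorized sub-aperture images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationResult
from .optics import RawLightField

__all__ = [
    "LightField4D", "EPI", "BackgroundModel", "decode_4d", "retile",
    "subaperture", "extract_epi", "brightest_epi_indices",
    "remove_background", "max_projection_epi",
]


@dataclass
class LightField4D:
    """4D light-field I4D(i, j, k, l), shape (N_i, N_j, K, L)."""
    data: np.ndarray
    edge_flags: np.ndarray | None = None   # (K, L) True where window clipped

    @property
    def n_views(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_lenslets(self) -> tuple[int, int]:
        return self.data.shape[2:]

    @property
    def total_intensity(self) -> float:
        return float(self.data.sum())


@dataclass
class EPI:
    """2D epipolar-plane image; axis 0 angular, axis 1 spatial."""
    data: np.ndarray
    orientation: str                 # "horizontal" (i-k) or "vertical" (j-l)
    fixed_indices: tuple[int, int]   # (j0, l0) or (i0, k0)

    def __post_init__(self):
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")


@dataclass
class BackgroundModel:
    """Leading singular triplet of the sub-aperture matrix A."""
    sigma_max: float
    u_max: np.ndarray
    v_max: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.sigma_max * np.outer(self.u_max, self.v_max)


def decode_4d(raw: RawLightField | np.ndarray,
              calib: CalibrationResult) -> LightField4D:
    """Rearrange the N_i x N_j pixel window around each detected lenslet
    centre (rounded to the nearest pixel) into I4D(:, :, k, l).

    Pixels falling outside the sensor are zero-filled and the lenslet is
    flagged as vignetted.  Total intensity of the extracted windows is
    conserved by construction.
    """
    image = raw.image if isinstance(raw, RawLightField) else np.asarray(raw)
    cfg = raw.config if isinstance(raw, RawLightField) else None
    if cfg is not None:
        n_i, n_j = cfg.pixels_per_lenslet
    else:
        n_i = n_j = int(round(calib.pitch_px))
    if calib.pitch_px < max(n_i, n_j) - 1e-9:
        raise ValueError("micro-image windows overlap: pitch "
                         f"{calib.pitch_px:.2f} px < window {max(n_i, n_j)} px")
    K, L = calib.centers.shape[:2]
    out = np.zeros((n_i, n_j, K, L), dtype=float)
    flags = np.zeros((K, L), dtype=bool)
    hr, hc = (n_i - 1) // 2, (n_j - 1) // 2
    for k in range(K):
        for l in range(L):
            r0 = int(round(calib.centers[k, l, 0])) - hr
            c0 = int(round(calib.centers[k, l, 1])) - hc
            rlo, rhi = max(r0, 0), min(r0 + n_i, image.shape[0])
            clo, chi = max(c0, 0), min(c0 + n_j, image.shape[1])
            if rlo >= rhi or clo >= chi:
                flags[k, l] = True
                continue
            win = np.zeros((n_i, n_j))
            win[rlo - r0:rhi - r0, clo - c0:chi - c0] = image[rlo:rhi, clo:chi]
            out[:, :, k, l] = win
            flags[k, l] = (rhi - rlo != n_i) or (chi - clo != n_j)
    return LightField4D(out, flags)


def retile(lf: LightField4D) -> np.ndarray:
    """Inverse rearrangement: tile micro-images back into a raw image of
    shape (K*N_i, L*N_j) (lenslets on a regular grid)."""
    n_i, n_j, K, L = lf.data.shape
    return lf.data.transpose(2, 0, 3, 1).reshape(K * n_i, L * n_j)


def subaperture(lf: LightField4D, i: int, j: int) -> np.ndarray:
    """The (K, L) sub-aperture image I4D(i, j, :, :); a pure view."""
    return lf.data[i, j]


def central_subaperture(lf: LightField4D) -> np.ndarray:
    n_i, n_j = lf.n_views
    return lf.data[n_i // 2, n_j // 2]


def extract_epi(lf: LightField4D, orientation: str,
                fixed_a: int, fixed_b: int,
                exclude_vignetted: bool = False) -> EPI:
    """Slice an EPI out of the 4D light-field.

    horizontal: fixed (j0, l0) -> I4D(:, j0, :, l0), axes (i, k);
    vertical:   fixed (i0, k0) -> I4D(i0, :, k0, :), axes (j, l).
    """
    n_i, n_j, K, L = lf.data.shape
    if orientation == "horizontal":
        j0, l0 = fixed_a, fixed_b
        if not (0 <= j0 < n_j and 0 <= l0 < L):
            raise IndexError("EPI indices out of range")
        data = lf.data[:, j0, :, l0]
        if exclude_vignetted and lf.edge_flags is not None:
            data = data[:, ~lf.edge_flags[:, l0]]
    elif orientation == "vertical":
        i0, k0 = fixed_a, fixed_b
        if not (0 <= i0 < n_i and 0 <= k0 < K):
            raise IndexError("EPI indices out of range")
        data = lf.data[i0, :, k0, :]
        if exclude_vignetted and lf.edge_flags is not None:
            data = data[:, ~lf.edge_flags[k0, :]]
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    return EPI(np.array(data), orientation, (fixed_a, fixed_b))


def brightest_epi_indices(lf: LightField4D) -> tuple[int, int]:
    """(k0, l0) of the brightest pixel of the central sub-aperture image —
    the default spatial position at which to extract the EPI pair."""
    sub = central_subaperture(lf)
    return tuple(int(v) for v in
                 np.unravel_index(int(np.argmax(sub)), sub.shape))


def extract_epi_pair(lf: LightField4D) -> tuple[EPI, EPI]:
    """Horizontal and vertical EPIs through the brightest pixel of the
    central sub-aperture image."""
    k0, l0 = brightest_epi_indices(lf)
    n_i, n_j = lf.n_views
    epi_h = extract_epi(lf, "horizontal", n_j // 2, l0)
    epi_v = extract_epi(lf, "vertical", n_i // 2, k0)
    return epi_h, epi_v


def remove_background(subapertures: np.ndarray
                      ) -> tuple[np.ndarray, BackgroundModel]:
    """Separate a scattering background from a stack of sub-aperture
    images via a rank-one SVD factorization.

    ``subapertures``: array (V, H, W) of V views.  The views are
    vectorized into the columns of a matrix A; the leading singular
    triplet forms the background B = u_max sigma_max v_max^T and the
    foreground A - B is reshaped back into images.
    """
    stack = np.asarray(subapertures, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 sub-aperture images")
    V, H, W = stack.shape
    A = stack.reshape(V, H * W).T              # (pixels, views)
    if not np.any(A):
        raise ValueError("all-zero sub-aperture stack")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    model = BackgroundModel(float(s[0]), U[:, 0].copy(), Vt[0].copy())
    fg = A - model.matrix
    return fg.T.reshape(V, H, W), model


def max_projection_epi(epi: EPI | np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row and per-column maxima of an EPI (diagnostic profiles that
    suppress diffuse background)."""
    data = epi.data if isinstance(epi, EPI) else np.asarray(epi)
    if data.size == 0:
        raise ValueError("empty EPI")
    return data.max(axis=1), data.max(axis=0)
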