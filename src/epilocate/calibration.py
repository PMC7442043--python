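"""MLA calibration from a raw, out-of-focus light-field image.

Three detectors, all deterministic:

* rotation angle — coarse-to-fine search maximizing the intensity
  contrast (max - min) of the high-pass-filtered column-sum profile;
* lenslet pitch — dominant non-DC peak of the column-sum spectrum,
  refined by parabolic interpolation;
* lenslet centres — convolution of the binarized image with a
  disc-shaped (or 3x3 multi-disc) kernel, window marching at the detected
  pitch, and a final per-row / per-column average that makes the centre
  grid exactly rectangular.

Pixel-centre coordinates are integers with (0, 0) the top-left pixel,
row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .config import OpticalConfig

__all__ = [
    "CalibrationResult", "ContrastCurve", "intensity_contrast",
    "detect_rotation_angle", "detect_pitch", "detect_centers",
    "disc_kernel", "calibrate", "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when a detector cannot find the lenslet grid structure."""


@dataclass
class CalibrationResult:
    rotation_angle_deg: float
    pitch_px: float
    centers: np.ndarray        # (K, L, 2) real-valued (row, col) coordinates

    @classmethod
    def ideal(cls, cfg: OpticalConfig) -> "CalibrationResult":
        """Nominal geometry: axis-aligned grid, centres at the middle pixel
        of each micro-image (odd pixels-per-lenslet assumed)."""
        K, L = cfg.lenslet_count
        n_i, n_j = cfg.pixels_per_lenslet
        rows = np.arange(K) * n_i + (n_i - 1) / 2.0
        cols = np.arange(L) * n_j + (n_j - 1) / 2.0
        centers = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1)
        return cls(0.0, float(n_i), centers)


@dataclass
class ContrastCurve:
    angles_deg: np.ndarray
    contrast: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def argmax(self) -> float:
        return float(self.angles_deg[int(np.argmax(self.contrast))])


def _rotate(image: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return image
    return ndimage.rotate(image, angle_deg, reshape=False, order=1,
                          mode="nearest")


def _highpass(vec: np.ndarray, cutoff_cycles: float) -> np.ndarray:
    # Butterworth order 3; cutoff in cycles/pixel (Nyquist = 0.5)
    b, a = signal.butter(3, cutoff_cycles / 0.5, btype="highpass")
    return signal.filtfilt(b, a, vec)


def intensity_contrast(image: np.ndarray, angle_deg: float,
                       cutoff_cycles: float = 0.02) -> float:
    """Rotate the image, sum along columns, high-pass the row vector to
    remove the DC component, and return max - min of the filtered vector.

    Only the central 70% of the rotated image enters the column sum:
    the corners of a rotated frame carry extrapolated pixels that would
    otherwise bias the contrast at larger angles.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0 or np.ptp(image) == 0:
        raise CalibrationError("image is constant; no grid contrast")
    rot = _rotate(image, angle_deg)
    mr, mc = int(0.15 * rot.shape[0]), int(0.15 * rot.shape[1])
    colsum = rot[mr:rot.shape[0] - mr, mc:rot.shape[1] - mc].sum(axis=0)
    filtered = _highpass(colsum, cutoff_cycles)
    return float(filtered.max() - filtered.min())


def contrast_curve(image: np.ndarray, angles_deg: np.ndarray,
                   cutoff_cycles: float = 0.02) -> ContrastCurve:
    vals = np.array([intensity_contrast(image, -a, cutoff_cycles)
                     for a in angles_deg])
    return ContrastCurve(np.asarray(angles_deg, dtype=float), vals)


def detect_rotation_angle(image: np.ndarray, coarse_range_deg: float = 5.0,
                          coarse_step_deg: float = 0.1,
                          cutoff_cycles: float = 0.02) -> float:
    """Coarse-to-fine rotation detection.

    Returns the angle the image is rotated by; rotating the image by the
    negated result aligns the lenslet grid with the pixel axes.  The fine
    pass spans +-1 degree around the coarse result at a tenth of the
    coarse step.
    """
    coarse = np.arange(-coarse_range_deg, coarse_range_deg + 1e-9,
                       coarse_step_deg)
    cc = contrast_curve(image, coarse, cutoff_cycles)
    if not np.isfinite(cc.contrast).all():
        raise CalibrationError("non-finite contrast curve")
    alpha = cc.argmax
    # sanity: the rotation-corrected column sum must be periodic, i.e.
    # show a distinct spectral peak; otherwise there is no lenslet grid
    corrected = _rotate(np.asarray(image, dtype=float), -alpha)
    sig = corrected.sum(axis=0)
    sig = sig - sig.mean()
    mag = np.abs(np.fft.rfft(sig * np.hanning(sig.size)))
    mag[0] = 0.0
    if np.ptp(sig) == 0 or mag.max() < 5.0 * np.median(mag[1:]):
        raise CalibrationError("no periodic lenslet structure detected "
                               "in the column-sum spectrum")
    fine_step = coarse_step_deg / 10.0
    fine = np.arange(alpha - 1.0, alpha + 1.0 + 1e-9, fine_step)
    fc = contrast_curve(image, fine, cutoff_cycles)
    return fc.argmax


def detect_pitch(image: np.ndarray) -> float:
    """Lenslet pitch (pixels) from the dominant frequency of the
    column-sum signal of a rotation-corrected image."""
    image = np.asarray(image, dtype=float)
    sig = image.sum(axis=0)
    sig = sig - sig.mean()
    if np.ptp(sig) == 0:
        raise CalibrationError("image has no column structure")
    w = np.hanning(sig.size)
    mag = np.abs(np.fft.rfft(sig * w))
    mag[0] = 0.0
    k = int(np.argmax(mag))
    if k == 0 or k >= mag.size - 1:
        raise CalibrationError("dominant frequency at DC or Nyquist")
    if mag[k] < 3.0 * np.median(mag[1:]):
        raise CalibrationError("spectral peak indistinct; cannot detect pitch")
    # parabolic refinement of the spectral peak
    denom = mag[k - 1] - 2 * mag[k] + mag[k + 1]
    delta = 0.0 if denom == 0 else 0.5 * (mag[k - 1] - mag[k + 1]) / denom
    freq = (k + delta) / sig.size
    pitch = 1.0 / freq
    if pitch <= 1.0:
        raise CalibrationError("detected pitch below one pixel")
    return float(pitch)


def disc_kernel(pitch_px: float, n_discs: int = 1) -> np.ndarray:
    """Binary kernel of ``n_discs x n_discs`` discs, each of diameter equal
    to the lenslet pitch, spaced by the pitch."""
    r = pitch_px / 2.0
    size = int(round(pitch_px))
    c = (size - 1) / 2.0
    yy, xx = np.indices((size, size))
    disc = ((yy - c) ** 2 + (xx - c) ** 2 <= r ** 2).astype(float)
    if n_discs == 1:
        return disc
    big = np.zeros((size * n_discs, size * n_discs))
    for a in range(n_discs):
        for b in range(n_discs):
            big[a * size:(a + 1) * size, b * size:(b + 1) * size] = disc
    return big


def detect_centers(image: np.ndarray, pitch_px: float,
                   threshold: float | None = None,
                   n_discs: int = 3,
                   grid_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Detect the K x L lenslet centre grid of a rotation-corrected image.

    Binarizes the image (Otsu when ``threshold`` is None), convolves with a
    disc/multi-disc kernel, marches a window of one pitch starting from the
    global response maximum snapping each centre to the local maximum
    within +-pitch/4, then averages along each row and column so the final
    map is a rectangular grid.  Returns an array of shape (K, L, 2) with
    real-valued (row, col) coordinates.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = threshold_otsu(image)
    binary = (image > threshold).astype(float)
    kernel = disc_kernel(pitch_px, n_discs)
    # mirror-pad by the kernel size: when the lenslet grid sits half a
    # pitch from the frame edge the reflection continues it periodically,
    # so border responses are not biased by kernel truncation
    pad = kernel.shape[0]
    padded = np.pad(binary, pad, mode="symmetric")
    conv = signal.fftconvolve(padded, kernel, mode="same")[pad:-pad, pad:-pad]

    if grid_shape is None:
        grid_shape = (int(image.shape[0] // pitch_px),
                      int(image.shape[1] // pitch_px))
    K, L = grid_shape

    seed = np.unravel_index(int(np.argmax(conv)), conv.shape)
    # phase of the grid: fold the seed back to the first cell
    first_row = seed[0] - round((seed[0] - pitch_px / 2) / pitch_px) * pitch_px
    first_col = seed[1] - round((seed[1] - pitch_px / 2) / pitch_px) * pitch_px

    snap = int(max(1, round(pitch_px / 4)))
    centers = np.full((K, L, 2), np.nan)
    missing = []
    for k in range(K):
        for l in range(L):
            er = first_row + k * pitch_px
            ec = first_col + l * pitch_px
            r0, c0 = int(round(er)), int(round(ec))
            rlo, rhi = max(r0 - snap, 0), min(r0 + snap + 1, conv.shape[0])
            clo, chi = max(c0 - snap, 0), min(c0 + snap + 1, conv.shape[1])
            win = conv[rlo:rhi, clo:chi]
            if win.size == 0 or win.max() <= 0:
                missing.append((k, l))
                continue
            # the response is flat wherever the kernel fully contains the
            # disc, so the "largest value" is a plateau; its centroid is
            # the centre (ties thereby break to the plateau middle)
            w = np.clip(win - 0.98 * win.max(), 0.0, None)
            yy, xx = np.indices(win.shape)
            centers[k, l] = ((w * yy).sum() / w.sum() + rlo,
                             (w * xx).sum() / w.sum() + clo)
    if missing:
        raise CalibrationError(f"no centre response for cells: {missing}")

    # per-row / per-column averaging -> rectangular grid
    row_coord = centers[:, :, 0].mean(axis=1)
    col_coord = centers[:, :, 1].mean(axis=0)
    return np.stack(np.meshgrid(row_coord, col_coord, indexing="ij"), axis=-1)


def calibrate(image: np.ndarray, n_discs: int = 3,
              threshold: float | None = None,
              grid_shape: tuple[int, int] | None = None) -> CalibrationResult:
    """Full calibration: angle, pitch, and centre grid from one raw image."""
    angle = detect_rotation_angle(image)
    corrected = _rotate(np.asarray(image, dtype=float), -angle)
    pitch = detect_pitch(corrected)
    centers = detect_centers(corrected, pitch, threshold=threshold,
                             n_discs=n_discs, grid_shape=grid_shape)
    return CalibrationResult(angle, pitch, centers)
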