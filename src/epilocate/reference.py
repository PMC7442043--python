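"""Direct spatial-domain reference solver for convolutional sparse coding.

Cross-validation oracle for the Fourier-domain ADMM solver: the same
objective

    1/2 || y - sum_m d_m (*) z_m ||_2^2 + beta sum_m || z_m ||_1

(circular convolution) is minimized by accelerated proximal gradient
descent (FISTA) using an *explicit* circulant convolution matrix — no
FFTs anywhere — so agreement of the two objectives is a genuine
two-route check of the transform-domain algebra.

1D signals only; intended for small problem sizes (N up to a few
hundred).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import circulant

__all__ = ["csc_objective_1d", "fista_csc_1d"]


def _conv_matrix(atom: np.ndarray, n: int) -> np.ndarray:
    """N x N circulant matrix implementing circular convolution with
    ``atom`` (zero-padded to length n)."""
    col = np.zeros(n)
    col[:atom.size] = atom
    return circulant(col)


def csc_objective_1d(y: np.ndarray, atoms: np.ndarray, z: np.ndarray,
                     beta: float) -> float:
    """Objective value evaluated with explicit matrix products."""
    n = y.size
    recon = np.zeros(n)
    for m in range(atoms.shape[0]):
        recon += _conv_matrix(atoms[m], n) @ z[m]
    return 0.5 * float(np.sum((y - recon) ** 2)) + beta * float(np.abs(z).sum())


def fista_csc_1d(y: np.ndarray, atoms: np.ndarray, beta: float,
                 n_iter: int = 5000) -> tuple[np.ndarray, float]:
    """FISTA on the 1D circular-convolution sparse coding problem.

    Returns (coefficient maps (M, N), final objective).
    """
    y = np.asarray(y, dtype=float)
    n, M = y.size, atoms.shape[0]
    A = np.hstack([_conv_matrix(atoms[m], n) for m in range(M)])  # (N, MN)
    L = float(np.linalg.eigvalsh(A.T @ A).max())
    if L == 0:
        raise ValueError("all-zero dictionary")
    step = 1.0 / L
    x = np.zeros(M * n)
    v = x.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = A.T @ (A @ v - y)
        u = v - step * grad
        x_new = np.sign(u) * np.maximum(np.abs(u) - beta * step, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        v = x_new + (t - 1) / t_new * (x_new - x)
        x, t = x_new, t_new
    z = x.reshape(M, n)
    obj = 0.5 * float(np.sum((A @ x - y) ** 2)) + beta * float(np.abs(x).sum())
    return z, obj
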