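"""3D localization by Fourier-domain ADMM convolutional sparse coding.

An observed EPI ``Y`` is represented as a sum of depth-aware dictionary
atoms ``d_m`` convolved with sparse coefficient maps ``z_m``:

    min_z  1/2 || Y - sum_m d_m * z_m ||_2^2 + beta sum_m || z_m ||_1.

ADMM splits the problem into a frequency-domain least-squares step
(diagonalized by the FFT; each frequency bin is a rank-one-plus-identity
system solved by the Sherman-Morrison identity), an elementwise
soft-threshold, and a dual update.  The index of the selected atom gives
the source depth via the dictionary lookup; the peak of its coefficient
map gives the lateral position; horizontal- and vertical-EPI estimates are
fused by reliability weights w = ||Z_Omega||_F^2 / ||Z||_F^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .config import OpticalConfig
from .decode import EPI
from .dictionary import EPIDictionary, transverse_sampling

__all__ = [
    "CSCProblem", "CSCResult", "LocalizationResult", "soft_threshold",
    "csc_admm", "cross_correlation", "default_beta", "select_sources",
    "compute_weight", "fuse_locations", "localize", "estimate_source_count",
]


@dataclass
class CSCProblem:
    """Inputs of one convolutional sparse coding solve."""
    observation: np.ndarray
    atoms: np.ndarray            # (M, *atom_shape)
    beta: float
    mu: float
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self):
        if self.beta <= 0 or self.mu <= 0:
            raise ValueError("beta and mu must be positive")
        if any(a > n for a, n in zip(self.atoms.shape[1:],
                                     self.observation.shape)):
            raise ValueError("atoms must be no larger than the observation")


@dataclass
class CSCResult:
    maps: np.ndarray             # (M, *obs_shape) sparse maps (T variable)
    z: np.ndarray                # least-squares variable at termination
    gamma: np.ndarray            # dual variable
    objective: list = field(default_factory=list)
    primal_residual: list = field(default_factory=list)
    n_iter: int = 0


@dataclass
class LocalizationResult:
    """Fused per-source 3D positions (object-space um) with diagnostics."""
    positions: np.ndarray        # (S, 3) = (x, y, z)
    omega_h: np.ndarray
    omega_v: np.ndarray
    w_h: float
    w_v: float
    p_h: np.ndarray              # (S, 3) horizontal-EPI estimates
    p_v: np.ndarray
    maps_h: np.ndarray | None = None
    maps_v: np.ndarray | None = None


def soft_threshold(x, lam: float):
    """S_lambda(x) = sign(x) (|x| - lambda)_+ elementwise."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def _pad_atoms(atoms: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros((atoms.shape[0],) + tuple(shape))
    sl = (slice(None),) + tuple(slice(0, s) for s in atoms.shape[1:])
    out[sl] = atoms
    return out


def cross_correlation(y: np.ndarray, atoms: np.ndarray) -> np.ndarray:
    """Circular cross-correlation of the observation with each atom,
    shape (M, *y.shape)."""
    axes = tuple(range(1, y.ndim + 1))
    D = sfft.fftn(_pad_atoms(atoms, y.shape), axes=axes)
    Yf = sfft.fftn(y)
    return sfft.ifftn(np.conj(D) * Yf[None], axes=axes).real


def default_beta(y: np.ndarray, atoms: np.ndarray,
                 fraction: float = 0.05) -> float:
    """Scale-free sparsity weight: ``fraction`` of the largest atom
    cross-correlation magnitude (the LASSO null threshold)."""
    return fraction * float(np.abs(cross_correlation(y, atoms)).max())


def csc_admm(problem: CSCProblem) -> CSCResult:
    """Solve the convolutional sparse coding problem by ADMM in the
    Fourier domain.

    Deterministic: Z, T and the dual start at zero.  Stops at ``max_iter``
    or when the relative primal residual ||Z - T|| / max(||Z||, ||T||)
    falls below ``tol``.  The returned ``maps`` are the (exactly sparse)
    T variable.
    """
    y = np.asarray(problem.observation, dtype=float)
    M = problem.atoms.shape[0]
    axes = tuple(range(1, y.ndim + 1))
    D = sfft.fftn(_pad_atoms(problem.atoms, y.shape), axes=axes)   # (M, ...)
    Dc = np.conj(D)
    Yf = sfft.fftn(y)
    mu, beta = problem.mu, problem.beta
    denom = mu + np.sum(np.abs(D) ** 2, axis=0)    # Sherman-Morrison scalar

    T = np.zeros((M,) + y.shape)
    gamma = np.zeros_like(T)
    Z = np.zeros_like(T)
    result = CSCResult(T, Z, gamma)

    for it in range(problem.max_iter):
        # Z-update: (D^H D + mu I)^-1 (D^H Y - gamma_hat + mu T_hat)
        b = Dc * Yf[None] + sfft.fftn(mu * T - gamma, axes=axes)
        s = np.sum(D * b, axis=0)
        with np.errstate(invalid="ignore"):
            Zf = (b - Dc * (s / denom)[None]) / mu
        Z = sfft.ifftn(Zf, axes=axes).real
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(f"ADMM diverged at iteration {it}")
        # T-update: soft threshold
        T = soft_threshold(Z + gamma / mu, beta / mu)
        # dual update
        gamma = gamma + mu * (Z - T)

        recon = sfft.ifftn(np.sum(D * sfft.fftn(Z, axes=axes), axis=0)).real
        obj = 0.5 * np.sum((y - recon) ** 2) + beta * np.abs(Z).sum()
        result.objective.append(float(obj))
        r = np.linalg.norm(Z - T)
        scale = max(np.linalg.norm(Z), np.linalg.norm(T), 1e-30)
        result.primal_residual.append(float(r / scale))
        result.n_iter = it + 1
        if result.primal_residual[-1] < problem.tol:
            break

    result.maps, result.z, result.gamma = T, Z, gamma
    return result


def map_energies(maps: np.ndarray, mask: np.ndarray | None = None
                 ) -> np.ndarray:
    m = maps if mask is None else maps * mask[None]
    return np.sum(m.reshape(maps.shape[0], -1) ** 2, axis=1)


def select_sources(maps: np.ndarray, S: int,
                   depths_um: np.ndarray | None = None,
                   min_depth_sep_um: float = 0.0,
                   mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Pick the S most energetic coefficient maps and their peak positions.

    Atoms whose depth lies within ``min_depth_sep_um`` of an already
    selected atom are suppressed, so one physical source does not consume
    several adjacent-depth atoms.  Returns (Omega, peak positions).
    """
    if S < 1 or S > maps.shape[0]:
        raise ValueError("need 1 <= S <= number of atoms")
    energies = map_energies(maps, mask)
    if np.count_nonzero(energies) < S:
        raise ValueError(
            f"only {np.count_nonzero(energies)} nonzero coefficient maps; "
            f"cannot select {S} sources")
    order = np.argsort(energies)[::-1]
    omega: list[int] = []
    for m in order:
        if energies[m] == 0:
            break
        if depths_um is not None and any(
                abs(depths_um[m] - depths_um[o]) <= min_depth_sep_um
                for o in omega):
            continue
        omega.append(int(m))
        if len(omega) == S:
            break
    if len(omega) < S:
        raise ValueError("could not select the requested number of sources "
                         "after depth-adjacency suppression")
    peaks = []
    for m in omega:
        zm = np.abs(maps[m] if mask is None else maps[m] * mask)
        peaks.append(tuple(int(v) for v in
                           np.unravel_index(int(np.argmax(zm)), zm.shape)))
    return np.array(omega), peaks


def estimate_source_count(maps: np.ndarray,
                          mask: np.ndarray | None = None) -> int:
    """Optional energy-gap heuristic for S: the largest relative drop in
    the sorted map-energy vector."""
    e = np.sort(map_energies(maps, mask))[::-1]
    e = e[e > 0]
    if e.size <= 1:
        return int(e.size)
    ratios = e[1:] / e[:-1]
    return int(np.argmin(ratios)) + 1


def compute_weight(maps: np.ndarray, omega) -> float:
    """Reliability weight w = ||Z_Omega||_F^2 / ||Z||_F^2 in [0, 1]."""
    total = float(np.sum(maps ** 2))
    if total == 0:
        raise ValueError("zero total coefficient energy")
    return float(np.sum(maps[np.asarray(omega, dtype=int)] ** 2)) / total


def fuse_locations(p_h: np.ndarray, p_v: np.ndarray,
                   w_h: float, w_v: float) -> np.ndarray:
    """Weighted average of the two per-EPI estimates with the weights
    renormalized to sum to one (convex combination)."""
    if w_h + w_v <= 0:
        raise ValueError("weights must not both be zero")
    return (w_h * np.asarray(p_h) + w_v * np.asarray(p_v)) / (w_h + w_v)


# ---------------------------------------------------------------------------
# End-to-end localization on an EPI pair
# ---------------------------------------------------------------------------

def _pad_epi(data: np.ndarray, atom_shape: tuple[int, int]
             ) -> tuple[np.ndarray, tuple[int, int]]:
    pa, ps = atom_shape
    return np.pad(data, ((pa, pa), (ps, ps))), (pa, ps)


def _valid_mask(canvas_shape, pads, atom_shape, anchor_col, n_spatial):
    """Coefficient positions whose atom placement aligns the atom's
    angular extent with the observed EPI rows and keeps the line centre
    inside the un-padded spatial range."""
    pa, ps = pads
    mask = np.zeros(canvas_shape, dtype=bool)
    qlo = ps - anchor_col
    mask[pa, qlo:qlo + n_spatial] = True
    return mask


def _solve_epi(epi: EPI, dic: EPIDictionary, S: int,
               beta: float | None, mu: float | None,
               max_iter: int, tol: float):
    canvas, pads = _pad_epi(epi.data, dic.atoms.shape[1:])
    b = default_beta(canvas, dic.atoms) if beta is None else beta
    m = 10.0 * b if mu is None else mu
    res = csc_admm(CSCProblem(canvas, dic.atoms, b, m, max_iter, tol))
    mask = _valid_mask(canvas.shape, pads, dic.atoms.shape[1:],
                       dic.anchor_col, epi.data.shape[1])
    omega, peaks = select_sources(res.maps, S, dic.depths_um,
                                  min_depth_sep_um=dic.depth_step_um,
                                  mask=mask)
    # spatial (lenslet) index of each source's line centre
    ks = [q + dic.anchor_col - pads[1] for (_, q) in peaks]
    return res, omega, ks


def _lenslet_to_object(cfg: OpticalConfig, idx: float, count: int) -> float:
    """Object-space lateral coordinate of lenslet ``idx`` (image inversion:
    larger object coordinate maps to smaller lenslet index)."""
    return (count - 1) / 2.0 - idx  # in lenslet units; scaled by caller


def localize(epi_h: EPI, epi_v: EPI, dict_h: EPIDictionary,
             dict_v: EPIDictionary | None = None, S: int = 1,
             beta: float | None = None, mu: float | None = None,
             max_iter: int = 200, tol: float = 1e-4,
             keep_maps: bool = False) -> LocalizationResult:
    """Full localization on a horizontal/vertical EPI pair.

    Runs the CSC solver on each EPI, selects S atoms per EPI, converts the
    selected atoms to depths and coefficient-map peaks to object-space
    lateral positions, computes the reliability weights, matches the two
    source lists by depth, and fuses them into final (x, y, z) positions.

    When ``beta`` is None it defaults to 5% of the largest observation/
    atom cross-correlation and ``mu`` to 10 beta.
    """
    if dict_v is None:
        dict_v = dict_h
    cfg = dict_h.config
    step = transverse_sampling(cfg)          # one lenslet in object um
    K, L = cfg.lenslet_count

    res_h, omega_h, ks_h = _solve_epi(epi_h, dict_h, S, beta, mu, max_iter, tol)
    res_v, omega_v, ls_v = _solve_epi(epi_v, dict_v, S, beta, mu, max_iter, tol)
    w_h = compute_weight(res_h.maps, omega_h)
    w_v = compute_weight(res_v.maps, omega_v)

    j0, l0 = epi_h.fixed_indices     # horizontal EPI fixed (j0, l0)
    i0, k0 = epi_v.fixed_indices     # vertical EPI fixed (i0, k0)

    p_h = np.array([[step * _lenslet_to_object(cfg, l0, L),
                     step * _lenslet_to_object(cfg, k, K),
                     dict_h.depth_lookup(m)]
                    for m, k in zip(omega_h, ks_h)])
    p_v = np.array([[step * _lenslet_to_object(cfg, l, L),
                     step * _lenslet_to_object(cfg, k0, K),
                     dict_v.depth_lookup(m)]
                    for m, l in zip(omega_v, ls_v)])

    # match sources between the two EPIs by depth (greedy nearest)
    order_h = np.argsort(p_h[:, 2])
    order_v = np.argsort(p_v[:, 2])
    p_h, p_v = p_h[order_h], p_v[order_v]
    omega_h, omega_v = omega_h[order_h], omega_v[order_v]

    fused = np.array([fuse_locations(ph, pv, w_h, w_v)
                      for ph, pv in zip(p_h, p_v)])
    return LocalizationResult(
        positions=fused, omega_h=omega_h, omega_v=omega_v,
        w_h=w_h, w_v=w_v, p_h=p_h, p_v=p_v,
        maps_h=res_h.maps if keep_maps else None,
        maps_v=res_v.maps if keep_maps else None)
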