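"""Reciprocal-space bookkeeping: cells, symmetry, reflections, normalization.

Symmetry handling is deliberately thin: native computation happens in P1 and
space-group information is only consulted for per-reflection metadata
(centric flags and the epsilon multiplicity factor) via gemmi's group
operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.integrate import trapezoid

VAR_PRIOR_ACENTRIC = 1.0 - np.pi / 4.0   # amplitude variance of the acentric Wilson prior
VAR_PRIOR_CENTRIC = 1.0 - 2.0 / np.pi


class UnitCell:
    """Triclinic unit cell with orthogonalization/fractionalization matrices."""

    def __init__(self, a, b, c, alpha=90.0, beta=90.0, gamma=90.0):
        for ang in (alpha, beta, gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"invalid cell angle {ang}")
        self._cell = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
        if self._cell.volume <= 0:
            raise ValueError("cell volume must be positive")
        self.a, self.b, self.c = a, b, c
        self.alpha, self.beta, self.gamma = alpha, beta, gamma
        self.orth = np.array(self._cell.orth.mat.tolist())
        self.frac = np.array(self._cell.frac.mat.tolist())

    @property
    def volume(self) -> float:
        return self._cell.volume

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth.T

    def s(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal resolution 1/d (A^-1) from the metric tensor."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        svec = hkl @ self.frac          # rows of frac are a*, b*, c*
        return np.linalg.norm(svec, axis=1)

    def to_gemmi(self) -> gemmi.UnitCell:
        return self._cell

    def __repr__(self):
        return (f"UnitCell({self.a}, {self.b}, {self.c}, "
                f"{self.alpha}, {self.beta}, {self.gamma})")


class SpaceGroupOps:
    """Closed set of symmetry operators of a space group.

    Rotations are integer 3x3 matrices acting on fractional coordinates;
    translations are fractions of the cell.
    """

    def __init__(self, name_or_ops="P 1"):
        if isinstance(name_or_ops, str):
            sg = gemmi.SpaceGroup(name_or_ops)
            self.name = sg.xhm()
            self._gops = sg.operations()
        else:
            self._gops = name_or_ops
            self.name = "custom"
        self.rotations = []
        self.translations = []
        for op in self._gops:
            self.rotations.append(np.array(op.rot, dtype=float) / op.DEN)
            self.translations.append(np.array(op.tran, dtype=float) / op.DEN)
        self.centrosymmetric = self._gops.is_centrosymmetric()

    def __len__(self):
        return len(self.rotations)

    def centric_and_epsilon(self, hkl: np.ndarray):
        """Brute-force operator application; matches gemmi on standard groups.

        centric(h): some rotation maps h -> -h.
        epsilon(h): number of rotations fixing h (counting identity).
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        centric = np.zeros(len(hkl), dtype=bool)
        epsilon = np.zeros(len(hkl), dtype=int)
        for rot in self.rotations:
            # reciprocal-space action: h' = h . R
            himg = np.rint(hkl @ rot).astype(int)
            centric |= np.all(himg == -hkl, axis=1)
            epsilon += np.all(himg == hkl, axis=1)
        return centric, epsilon


@dataclass
class ReflectionSet:
    """Observed reflections with metadata and derived likelihood inputs."""

    hkl: np.ndarray                       # (n, 3) int
    s: np.ndarray                         # 1/d, A^-1
    epsilon: np.ndarray                   # multiplicity factor
    centric: np.ndarray                   # bool
    I_o: np.ndarray | None = None
    sigma_I: np.ndarray | None = None
    E_e: np.ndarray | None = None
    D_obs: np.ndarray | None = None
    bin_id: np.ndarray | None = None
    free_flag: np.ndarray | None = None
    wilson_scale: np.ndarray | None = None  # per-bin mean normalized intensity

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))

    def __len__(self):
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return 1.0 / self.s

    @property
    def n_bins(self) -> int:
        return int(self.bin_id.max()) + 1 if self.bin_id is not None else 0

    def work_mask(self) -> np.ndarray:
        if self.free_flag is None:
            return np.ones(len(self), dtype=bool)
        return ~self.free_flag

    def resolution_mask(self, d_min: float | None = None,
                        d_max: float | None = None) -> np.ndarray:
        mask = np.ones(len(self), dtype=bool)
        if d_min is not None:
            mask &= self.d >= d_min
        if d_max is not None:
            mask &= self.d <= d_max
        return mask


def reflection_metadata(cell: UnitCell, ops: SpaceGroupOps,
                        hkl: np.ndarray) -> ReflectionSet:
    """Skeleton ReflectionSet with resolution, epsilon and centric flags."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    if len(hkl) == 0:
        raise ValueError("empty hkl list")
    if np.any(np.all(hkl == 0, axis=1)):
        raise ValueError("the (0,0,0) index is not a reflection")
    s = cell.s(hkl)
    centric, epsilon = ops.centric_and_epsilon(hkl)
    return ReflectionSet(hkl=hkl, s=s, epsilon=epsilon.astype(float),
                         centric=centric)


def assign_bins(refl: ReflectionSet, n_bins: int = 20,
                min_per_bin: int = 50) -> ReflectionSet:
    """Equal-count resolution bins in s; small tails are merged."""
    n = len(refl)
    n_bins = max(1, min(n_bins, n // max(min_per_bin, 1)))
    order = np.argsort(refl.s, kind="stable")
    bin_id = np.empty(n, dtype=int)
    # equal-count split of the s-sorted list
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bin_id[idx] = b
    refl.bin_id = bin_id
    return refl


def assign_free_flags(refl: ReflectionSet, fraction: float = 0.05,
                      seed: int = 0) -> ReflectionSet:
    rng = np.random.default_rng(seed)
    refl.free_flag = rng.random(len(refl)) < fraction
    return refl


def normalize_to_E(amplitudes: np.ndarray, refl: ReflectionSet) -> np.ndarray:
    """Binned Wilson normalization: E = |F| / sqrt(eps * <|F|^2/eps>_bin)."""
    if refl.bin_id is None:
        raise ValueError("bins not assigned; call assign_bins first")
    amplitudes = np.abs(np.asarray(amplitudes, dtype=float))
    E = np.empty_like(amplitudes)
    for b in range(refl.n_bins):
        sel = refl.bin_id == b
        if not sel.any():
            raise ValueError(f"empty resolution bin {b}")
        scale = np.mean(amplitudes[sel] ** 2 / refl.epsilon[sel])
        E[sel] = amplitudes[sel] / np.sqrt(refl.epsilon[sel] * scale)
    return E


def _posterior_moments(z, sigma_z, centric, grid_points=801, e_max=6.0):
    """Moments of the truncated-Wilson posterior over the true normalized
    amplitude E given a normalized intensity observation z ~ N(E^2, sigma_z^2).

    Vectorized quadrature on a fixed E grid; returns (m1, m2).
    """
    e = np.linspace(0.0, e_max, grid_points)
    prior_a = 2.0 * e * np.exp(-e ** 2)
    prior_c = np.sqrt(2.0 / np.pi) * np.exp(-e ** 2 / 2.0)
    prior = np.where(centric[:, None], prior_c[None, :], prior_a[None, :])
    resid = (z[:, None] - e[None, :] ** 2) / sigma_z[:, None]
    log_like = -0.5 * resid ** 2
    log_like -= log_like.max(axis=1, keepdims=True)
    w = prior * np.exp(log_like)
    norm = trapezoid(w, e, axis=1)
    norm = np.where(norm > 0, norm, 1.0)
    m1 = trapezoid(w * e, e, axis=1) / norm
    m2 = trapezoid(w * e ** 2, e, axis=1) / norm
    return m1, m2


def effective_amplitudes(I_o: np.ndarray, sigma_I: np.ndarray,
                         refl: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
    """Effective normalized amplitudes E_e and the error attenuation D_obs.

    Moment matching on the truncated-Wilson posterior: E_e is the posterior
    mean amplitude and D_obs = sqrt(1 - Var_post/Var_prior), which is 1 for a
    noiseless observation and 0 when the measurement carries no information
    (posterior = prior). Intensities are first put on the normalized scale
    z = I / (eps * <I/eps>_bin).
    """
    I_o = np.asarray(I_o, dtype=float)
    sigma_I = np.asarray(sigma_I, dtype=float)
    if np.any(sigma_I <= 0):
        raise ValueError("sigma_I must be positive")
    if refl.bin_id is None:
        raise ValueError("bins not assigned; call assign_bins first")

    z = np.empty_like(I_o)
    sigma_z = np.empty_like(I_o)
    wilson_scale = np.empty(refl.n_bins)
    for b in range(refl.n_bins):
        sel = refl.bin_id == b
        mean_i = np.mean(I_o[sel] / refl.epsilon[sel])
        if mean_i <= 0:
            warnings.warn(f"non-positive mean intensity in bin {b}; "
                          "proceeding with a positive floor")
            mean_i = np.mean(np.abs(I_o[sel]) / refl.epsilon[sel]) or 1.0
        wilson_scale[b] = mean_i
        z[sel] = I_o[sel] / (refl.epsilon[sel] * mean_i)
        sigma_z[sel] = sigma_I[sel] / (refl.epsilon[sel] * mean_i)

    m1, m2 = _posterior_moments(z, sigma_z, refl.centric)
    var_post = np.maximum(m2 - m1 ** 2, 0.0)
    var_prior = np.where(refl.centric, VAR_PRIOR_CENTRIC, VAR_PRIOR_ACENTRIC)
    D_obs = np.sqrt(np.clip(1.0 - var_post / var_prior, 0.0, 1.0))
    refl.E_e = m1
    refl.D_obs = D_obs
    refl.wilson_scale = wilson_scale
    return m1, D_obs
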