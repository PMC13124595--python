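"""Cryo-EM Fourier-term log-likelihood-gain target.

Signal and noise are estimated per resolution shell from the two half-maps:
the cross-term Re<F1 conj(F2)> measures shared signal, the half-map
difference measures noise. Each Fourier term of the averaged map then
carries an observed normalized amplitude E_e and phase phi_obs, a shell
attenuation D_obs, and the per-term LLG

    LLG = 2 t E_e E_calc cos(dphi) / (1 - t^2)
          - t^2 (E_e^2 + E_calc^2) / (1 - t^2) - ln(1 - t^2)

with t = D_obs * sigma_A and dphi = phi_calc - phi_obs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .model import AtomicModel
from .map_simulation import grid_frequencies, make_shells
from .reciprocal import UnitCell
from .structure_factors import (
    DirectSummation,
    ModelStructureFactors,
    amplitude_cotangent,
    normalized_amplitude_vjp,
)
from .xtal_target import SIGMA_A_MAX, SIGMA_A_MIN


@dataclass
class HalfMapFourier:
    """Paired half-map Fourier terms with shell noise statistics."""

    F_1: np.ndarray
    F_2: np.ndarray
    s: np.ndarray
    shell_id: np.ndarray
    shell_centers: np.ndarray
    signal: np.ndarray            # per shell, averaged-map signal power
    noise: np.ndarray             # per shell, averaged-map noise power
    E_e: np.ndarray               # per term
    phi_obs: np.ndarray           # per term, rad
    D_obs: np.ndarray             # per shell
    sigma_a: np.ndarray | None = None

    @property
    def n_shells(self) -> int:
        return len(self.shell_centers)

    def dobs_per_term(self) -> np.ndarray:
        return self.D_obs[self.shell_id]

    def sigma_a_per_term(self) -> np.ndarray:
        return self.sigma_a[self.shell_id]


def halfmap_statistics(F_1: np.ndarray, F_2: np.ndarray, s: np.ndarray,
                       shell_id: np.ndarray,
                       shell_centers: np.ndarray) -> HalfMapFourier:
    """Shell-wise signal/noise moments and per-term observed quantities.

    Signal S = max(0, Re<F1 conj F2>) per shell; noise N = <|F1-F2|^2>/4 is
    the noise power of one averaged-map term. D_obs^2 = S/(S+N); the
    averaged map's terms are normalized by sqrt(S+N).
    """
    if F_1.shape != F_2.shape:
        raise ValueError("half-map Fourier arrays must share a grid")
    F_1 = np.asarray(F_1).ravel()
    F_2 = np.asarray(F_2).ravel()
    s = np.asarray(s, dtype=float).ravel()
    shell_id = np.asarray(shell_id).ravel()
    n_shells = len(shell_centers)
    signal = np.zeros(n_shells)
    noise = np.zeros(n_shells)
    D_obs = np.zeros(n_shells)
    favg = 0.5 * (F_1 + F_2)
    E_e = np.zeros(len(favg))
    for b in range(n_shells):
        sel = shell_id == b
        if not sel.any():
            continue
        signal[b] = max(0.0, float(np.real(np.mean(F_1[sel]
                                                   * np.conj(F_2[sel])))))
        noise[b] = 0.25 * float(np.mean(np.abs(F_1[sel] - F_2[sel]) ** 2))
        total = signal[b] + noise[b]
        if total <= 0:
            warnings.warn(f"all-zero shell {b}; D_obs set to 0")
            continue
        D_obs[b] = np.sqrt(signal[b] / total)
        E_e[sel] = np.abs(favg[sel]) / np.sqrt(total)
    return HalfMapFourier(F_1=F_1, F_2=F_2, s=s, shell_id=shell_id,
                          shell_centers=np.asarray(shell_centers),
                          signal=signal, noise=noise, E_e=E_e,
                          phi_obs=np.angle(favg), D_obs=D_obs)


def _llg_terms_em(E_e, E_calc, dphi, t):
    """Per-term LLG value plus derivatives in (E_calc, phi_calc)."""
    if np.any(t >= 1.0):
        raise ValueError("D_obs*sigma_A must stay below 1")
    u = 1.0 - t ** 2
    cos = np.cos(dphi)
    terms = (2.0 * t * E_e * E_calc * cos / u
             - t ** 2 * (E_e ** 2 + E_calc ** 2) / u
             - np.log(u))
    g_ec = 2.0 * t * E_e * cos / u - 2.0 * t ** 2 * E_calc / u
    g_phi = -2.0 * t * E_e * E_calc * np.sin(dphi) / u
    return terms, g_ec, g_phi


def llg_cryoem(hm: HalfMapFourier, sf: ModelStructureFactors):
    """Total LLG over all terms; returns (value, dL/dE_calc, dL/dphi_calc)."""
    t = hm.dobs_per_term() * hm.sigma_a_per_term()
    dphi = sf.phi_calc - hm.phi_obs
    terms, g_ec, g_phi = _llg_terms_em(hm.E_e, sf.E_C, dphi, t)
    return float(np.sum(terms)), g_ec, g_phi


def sigma_a_em(hm: HalfMapFourier, sf: ModelStructureFactors) -> np.ndarray:
    """Per-shell sigma_A maximizing the shell's LLG sum, clamped."""
    dphi = sf.phi_calc - hm.phi_obs
    out = np.empty(hm.n_shells)
    for b in range(hm.n_shells):
        sel = hm.shell_id == b
        if not sel.any() or hm.D_obs[b] <= 0:
            warnings.warn(f"degenerate shell {b}; sigma_A at lower clamp")
            out[b] = SIGMA_A_MIN
            continue
        ee, ec, dp = hm.E_e[sel], sf.E_C[sel], dphi[sel]
        dob = hm.D_obs[b]

        def neg(sig):
            return -np.sum(_llg_terms_em(ee, ec, dp, dob * sig)[0])

        res = minimize_scalar(neg, bounds=(SIGMA_A_MIN, SIGMA_A_MAX),
                              method="bounded",
                              options={"xatol": 1e-5})
        out[b] = float(res.x)
    hm.sigma_a = out
    return out


def model_map(model: AtomicModel, cell: UnitCell, shape,
              d_min: float | None = 2.0) -> np.ndarray:
    """Model-derived density on a real-space grid (inverse FFT of the
    model's Fourier terms, band-limited to d_min)."""
    hkl, s = grid_frequencies(shape, cell)
    flat_hkl = hkl.reshape(-1, 3)
    flat_s = s.ravel()
    keep = np.ones(len(flat_s), dtype=bool)
    if d_min is not None:
        keep &= flat_s <= 1.0 / d_min
    F = np.zeros(len(flat_s), dtype=complex)
    # numpy's forward-FFT sign convention: use -hkl in the crystallographic sum
    calc = DirectSummation(cell, -flat_hkl[keep], flat_s[keep],
                           model.elements, model.occupancy)
    F[keep] = calc.compute(model.xyz, model.b_iso)
    F = F.reshape(s.shape)
    vol = cell.volume
    return np.fft.irfftn(F, s=shape) * (np.prod(shape) / vol)


def rscc(model: AtomicModel, map_grid: np.ndarray, cell: UnitCell,
         per_residue: bool = False, d_min: float | None = 2.0,
         mask_radius: float = 2.5):
    """Real-space Pearson correlation between model-derived and experimental
    density, globally or over per-residue masks."""
    calc_map = model_map(model, cell, map_grid.shape, d_min=d_min)
    shape = np.array(map_grid.shape)
    frac = cell.fractionalize(model.xyz)

    def _mask(atom_sel):
        m = np.zeros(map_grid.shape, dtype=bool)
        for fx in frac[atom_sel]:
            center = fx * shape
            # bounding box of the mask sphere, with periodic wrap
            rad_vox = mask_radius / (cell.volume ** (1 / 3) / shape.mean()) + 1
            lo = np.floor(center - rad_vox).astype(int)
            hi = np.ceil(center + rad_vox).astype(int)
            ix = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
            gx, gy, gz = np.meshgrid(*ix, indexing="ij")
            vox = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
            cart = cell.orthogonalize(vox / shape)
            dist = np.linalg.norm(cart - cell.orthogonalize(fx), axis=1)
            near = vox[dist <= mask_radius] % shape
            m[near[:, 0], near[:, 1], near[:, 2]] = True
        return m

    def _pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))
        return float(np.sum(a * b) / den) if den > 0 else float("nan")

    if not per_residue:
        return _pearson(calc_map.ravel(), map_grid.ravel())

    values = np.full(model.n_residues, np.nan)
    for res in range(model.n_residues):
        m = _mask(model.resid == res)
        if not m.any():
            warnings.warn(f"residue {res} outside map; RSCC undefined")
            continue
        values[res] = _pearson(calc_map[m], map_grid[m])
    return values


def update_b_from_rscc(model: AtomicModel, map_grid: np.ndarray,
                       cell: UnitCell, b_min: float = 20.0,
                       b_max: float = 300.0) -> np.ndarray:
    """Per-residue B from local RSCC: a linear, monotone non-increasing map
    with RSCC >= 1 pinned to b_min and RSCC <= 0 pinned to b_max."""
    cc = rscc(model, map_grid, cell, per_residue=True)
    cc = np.where(np.isnan(cc), 0.0, cc)
    return b_min + (b_max - b_min) * (1.0 - np.clip(cc, 0.0, 1.0))


class EMTarget:
    """Callable cryo-EM LLG target over model coordinates and B.

    Precomputes half-map statistics once; each evaluation recomputes the
    model's Fourier terms at the retained indices, renormalizes per shell,
    refits sigma_A, and pulls gradients back to coordinates and B factors.
    """

    def __init__(self, map1: np.ndarray, map2: np.ndarray, cell: UnitCell,
                 elements, occupancy, d_min: float | None = None,
                 refit_sigma_a: bool = True, min_terms_per_shell: int = 50):
        if map1.shape != map2.shape:
            raise ValueError("half-maps must share a grid")
        self.cell = cell
        F1 = np.fft.rfftn(map1)
        F2 = np.fft.rfftn(map2)
        hkl, s = grid_frequencies(map1.shape, cell)
        flat_hkl = hkl.reshape(-1, 3)
        flat_s = s.ravel()
        keep = flat_s > 0
        if d_min is not None:
            keep &= flat_s <= 1.0 / d_min
        self.hkl = flat_hkl[keep]
        self.s = flat_s[keep]
        shell_id, centers = make_shells(self.s,
                                        min_terms=min_terms_per_shell)
        self.hm = halfmap_statistics(F1.ravel()[keep], F2.ravel()[keep],
                                     self.s, shell_id, centers)
        self.calc = DirectSummation(cell, -self.hkl, self.s, elements,
                                    occupancy)
        self.refit_sigma_a = refit_sigma_a
        self.shell_id = shell_id
        self.res_mask = np.ones(len(self.s), dtype=bool)

    def set_resolution_window(self, d_min: float | None = None,
                              d_max: float | None = None):
        """Restrict the active terms; d >= d_min keeps only low resolution."""
        mask = np.ones(len(self.s), dtype=bool)
        if d_min is not None:
            mask &= self.s <= 1.0 / d_min
        if d_max is not None:
            mask &= self.s >= 1.0 / d_max
        self.res_mask = mask

    def structure_factors(self, xyz, b_iso) -> ModelStructureFactors:
        F = self.calc.compute(xyz, b_iso)
        sf = ModelStructureFactors(F_c=F)
        amp = np.abs(F)
        E = np.empty_like(amp)
        for b in range(self.hm.n_shells):
            sel = self.shell_id == b
            scale = np.mean(amp[sel] ** 2)
            E[sel] = amp[sel] / np.sqrt(scale) if scale > 0 else 0.0
        sf.E_C = E
        return sf

    def loss_and_gradients(self, xyz, b_iso):
        sf = self.structure_factors(xyz, b_iso)
        if self.refit_sigma_a or self.hm.sigma_a is None:
            sigma_a_em(self.hm, sf)
        t = self.hm.dobs_per_term() * self.hm.sigma_a_per_term()
        dphi = sf.phi_calc - self.hm.phi_obs
        terms, g_ec, g_phi = _llg_terms_em(self.hm.E_e, sf.E_C, dphi, t)
        mask = self.res_mask
        value = float(np.sum(terms[mask]))
        g_ec = np.where(mask, g_ec, 0.0)
        g_phi = np.where(mask, g_phi, 0.0)
        g_amp = normalized_amplitude_vjp(
            np.abs(sf.F_c), np.ones(len(self.s)), self.shell_id, g_ec)
        gF = amplitude_cotangent(sf.F_c, g_amp, g_phase=g_phi)
        gx, gb = self.calc.vjp(gF)
        return value, gx, gb

    def llg(self, xyz, b_iso) -> float:
        return self.loss_and_gradients(xyz, b_iso)[0]
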