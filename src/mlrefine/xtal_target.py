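"""Intensity-based crystallographic log-likelihood-gain target (LLGI).

The LLGI compares, reflection by reflection, the probability of the
effective observed normalized amplitude E_e given the model's normalized
amplitude E_C against its probability under the uninformative Wilson
distribution. Model and measurement quality enter through the product
d = D_obs * sigma_A: acentric reflections follow a Rice distribution,
centric ones a Woolfson (folded-normal-like) distribution, both with
variance 1 - d^2.

All Bessel/cosh factors are evaluated in log space so the target is stable
for the large arguments that arise with good models at high resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .reciprocal import ReflectionSet, normalize_to_E
from .structure_factors import (
    DirectSummation,
    ModelStructureFactors,
    amplitude_cotangent,
    normalized_amplitude_vjp,
)

SIGMA_A_MIN = 0.015
SIGMA_A_MAX = 0.99


def _log_i0(z):
    return np.log(i0e(z)) + z


def _log_cosh(w):
    aw = np.abs(w)
    return aw + np.log1p(np.exp(-2.0 * aw)) - np.log(2.0)


def conditional_density(E_e, E_C, d, centric, log=False):
    """p(E_e; E_C) with correlation parameter d = D_obs * sigma_A.

    Rice form for acentric reflections, Woolfson (cosh) form for centric
    ones. ``d`` must satisfy 0 <= d < 1; at d = 0 both reduce to the Wilson
    null distributions.
    """
    E_e = np.asarray(E_e, dtype=float)
    E_C = np.asarray(E_C, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d >= 1):
        raise ValueError("need 0 <= D_obs*sigma_A < 1 (variance 1-d^2 > 0)")
    centric = np.asarray(centric, dtype=bool)
    u = 1.0 - d ** 2
    with np.errstate(divide="ignore"):
        log_pa = (np.log(2.0 * E_e) - np.log(u)
                  - (E_e ** 2 + (d * E_C) ** 2) / u
                  + _log_i0(2.0 * d * E_e * E_C / u))
        log_pc = (0.5 * np.log(2.0 / np.pi) - 0.5 * np.log(u)
                  - (E_e ** 2 + (d * E_C) ** 2) / (2.0 * u)
                  + _log_cosh(d * E_e * E_C / u))
    out = np.where(centric, log_pc, log_pa)
    return out if log else np.exp(out)


def llgi_terms(E_e, E_C, d, centric):
    """Per-reflection LLGI contribution and its derivative in E_C."""
    E_e = np.asarray(E_e, dtype=float)
    E_C = np.asarray(E_C, dtype=float)
    d = np.asarray(d, dtype=float)
    centric = np.asarray(centric, dtype=bool)
    u = 1.0 - d ** 2
    za = 2.0 * d * E_e * E_C / u
    wa = d * E_e * E_C / u
    terms_a = (-np.log(u) - (E_e ** 2 + (d * E_C) ** 2) / u + E_e ** 2
               + _log_i0(za))
    terms_c = (-0.5 * np.log(u) - (E_e ** 2 + (d * E_C) ** 2) / (2.0 * u)
               + E_e ** 2 / 2.0 + _log_cosh(wa))
    terms = np.where(centric, terms_c, terms_a)
    ratio = i1e(za) / i0e(za)
    grad_a = -2.0 * d ** 2 * E_C / u + ratio * 2.0 * d * E_e / u
    grad_c = -(d ** 2) * E_C / u + np.tanh(wa) * d * E_e / u
    grad = np.where(centric, grad_c, grad_a)
    if np.isnan(terms).any():
        bad = int(np.flatnonzero(np.isnan(terms))[0])
        raise FloatingPointError(f"NaN LLGI term at reflection {bad}")
    return terms, grad


@dataclass
class SigmaABins:
    """Per-bin sigma_A estimates with refinement diagnostics."""

    bin_s_centers: np.ndarray
    sigma_a: np.ndarray
    n_steps: np.ndarray | None = None
    final_gradient: np.ndarray | None = None

    def per_reflection(self, bin_id: np.ndarray) -> np.ndarray:
        return self.sigma_a[bin_id]


def llgi(refl: ReflectionSet, sf: ModelStructureFactors, sigA: SigmaABins,
         mask: np.ndarray | None = None):
    """Total LLGI over the (masked) working set.

    Returns (value, per_reflection_dLLGI/dE_C) with the gradient zero
    outside the mask.
    """
    if mask is None:
        mask = refl.work_mask()
    else:
        mask = np.asarray(mask, dtype=bool) & refl.work_mask()
    d = refl.D_obs * sigA.per_reflection(refl.bin_id)
    terms, grad = llgi_terms(refl.E_e, sf.E_C, d, refl.centric)
    grad_out = np.where(mask, grad, 0.0)
    return float(np.sum(terms[mask])), grad_out


def _bin_llg_and_derivative(E_e, E_C, D_obs, centric, sigma_a):
    """Sum of LLGI over one bin and its analytic d/dsigma_A."""
    d = D_obs * sigma_a
    u = 1.0 - d ** 2
    terms, _ = llgi_terms(E_e, E_C, d, centric)
    za = 2.0 * d * E_e * E_C / u
    ratio = i1e(za) / i0e(za)
    dd_a = (2.0 * d / u - 2.0 * d * (E_e ** 2 + E_C ** 2) / u ** 2
            + ratio * 2.0 * E_e * E_C * (1.0 + d ** 2) / u ** 2)
    wa = d * E_e * E_C / u
    dd_c = (d / u - d * (E_e ** 2 + E_C ** 2) / u ** 2
            + np.tanh(wa) * E_e * E_C * (1.0 + d ** 2) / u ** 2)
    dterm = np.where(centric, dd_c, dd_a) * D_obs
    return float(np.sum(terms)), float(np.sum(dterm))


def _refine_sigma_a_bin(E_e, E_C, D_obs, centric, sigma0=0.5, tol=1e-4,
                        max_steps=20):
    """Newton iteration on one bin's sigma_A, clamped to the legal interval.

    The first derivative is analytic; the curvature is obtained by central
    differencing of the analytic gradient, and any non-concave step falls
    back to a golden-section-style bisection toward the gradient direction.
    """
    lo, hi = SIGMA_A_MIN, SIGMA_A_MAX
    # monotone boundary cases: the optimum sits on a clamp
    g_lo = _bin_llg_and_derivative(E_e, E_C, D_obs, centric, lo)[1]
    g_hi = _bin_llg_and_derivative(E_e, E_C, D_obs, centric, hi)[1]
    if g_lo <= 0:
        return lo, 0, g_lo
    if g_hi >= 0:
        return hi, 0, g_hi
    sig = float(np.clip(sigma0, lo, hi))
    h = 1e-4
    steps = 0
    grad = 0.0
    for steps in range(1, max_steps + 1):
        _, grad = _bin_llg_and_derivative(E_e, E_C, D_obs, centric, sig)
        gp = _bin_llg_and_derivative(E_e, E_C, D_obs, centric,
                                     min(sig + h, hi))[1]
        gm = _bin_llg_and_derivative(E_e, E_C, D_obs, centric,
                                     max(sig - h, lo))[1]
        curv = (gp - gm) / (min(sig + h, hi) - max(sig - h, lo))
        if curv < 0:
            step = -grad / curv
        else:
            warnings.warn("non-concave sigma_A point; bisection fallback")
            step = 0.1 * np.sign(grad)
        new = float(np.clip(sig + step, lo, hi))
        if abs(new - sig) < tol:
            sig = new
            break
        sig = new
    return sig, steps, grad


def refine_sigma_a(refl: ReflectionSet, sf: ModelStructureFactors,
                   sigma0: float | np.ndarray = 0.5,
                   mask: np.ndarray | None = None) -> SigmaABins:
    """Per-bin maximum-likelihood sigma_A by Newton-Raphson, on the working
    set, clamped to [0.015, 0.99]."""
    if mask is None:
        mask = refl.work_mask()
    else:
        mask = np.asarray(mask, dtype=bool) & refl.work_mask()
    n_bins = refl.n_bins
    sigma0 = np.broadcast_to(np.asarray(sigma0, dtype=float), (n_bins,))
    sig = np.empty(n_bins)
    steps = np.empty(n_bins, dtype=int)
    grads = np.empty(n_bins)
    centers = np.empty(n_bins)
    for b in range(n_bins):
        sel = (refl.bin_id == b) & mask
        centers[b] = float(np.mean(refl.s[refl.bin_id == b]))
        if sel.sum() < 3:
            sig[b], steps[b], grads[b] = SIGMA_A_MIN, 0, 0.0
            continue
        sig[b], steps[b], grads[b] = _refine_sigma_a_bin(
            refl.E_e[sel], sf.E_C[sel], refl.D_obs[sel], refl.centric[sel],
            sigma0=sigma0[b],
        )
    return SigmaABins(bin_s_centers=centers, sigma_a=sig, n_steps=steps,
                      final_gradient=grads)


def r_factors(F_obs: np.ndarray, F_calc: np.ndarray,
              free_flags: np.ndarray | None = None):
    """(R_work, R_free) with a least-squares scale fitted on the work set."""
    ao = np.abs(np.asarray(F_obs, dtype=float))
    ac = np.abs(np.asarray(F_calc, dtype=float))
    if free_flags is None:
        free_flags = np.zeros(len(ao), dtype=bool)
    free_flags = np.asarray(free_flags, dtype=bool)
    work = ~free_flags
    if not work.any():
        raise ValueError("empty working set")
    k = float(np.sum(ao[work] * ac[work]) / np.sum(ac[work] ** 2))

    def _r(sel):
        return float(np.sum(np.abs(ao[sel] - k * ac[sel])) / np.sum(ao[sel]))

    r_work = _r(work)
    if free_flags.any():
        r_free = _r(free_flags)
    else:
        warnings.warn("empty free set; R_free undefined")
        r_free = float("nan")
    return r_work, r_free


class XtalTarget:
    """Callable crystallographic LLGI target over model coordinates and B.

    Bundles the reflection data, the structure-factor engine and per-bin
    sigma_A refitting into the loss/gradient interface the refinement engine
    and rigid-body refiner consume. sigma_A is refit (Newton) at each
    evaluation unless frozen; within one evaluation it is treated as a
    constant of the gradient, which is exact to first order at its
    per-bin optimum.
    """

    def __init__(self, refl: ReflectionSet, cell, elements, occupancy,
                 ops=None, d_min: float | None = None,
                 d_max: float | None = None, refit_sigma_a: bool = True):
        self.refl = refl
        self.cell = cell
        self.calc = DirectSummation(cell, refl.hkl, refl.s, elements,
                                    occupancy, ops=ops)
        self.res_mask = refl.resolution_mask(d_min=d_min, d_max=d_max)
        self.refit_sigma_a = refit_sigma_a
        self.sigma_a_bins: SigmaABins | None = None

    def set_resolution_window(self, d_min=None, d_max=None):
        self.res_mask = self.refl.resolution_mask(d_min=d_min, d_max=d_max)

    def structure_factors(self, xyz, b_iso) -> ModelStructureFactors:
        F = self.calc.compute(xyz, b_iso)
        sf = ModelStructureFactors(F_c=F)
        sf.E_C = normalize_to_E(np.abs(F), self.refl)
        return sf

    def loss_and_gradients(self, xyz, b_iso):
        """(llg, dllg/dxyz, dllg/db_iso) on the masked working set."""
        sf = self.structure_factors(xyz, b_iso)
        if self.refit_sigma_a or self.sigma_a_bins is None:
            self.sigma_a_bins = refine_sigma_a(
                self.refl, sf,
                sigma0=(self.sigma_a_bins.sigma_a
                        if self.sigma_a_bins is not None else 0.5),
                mask=self.res_mask,
            )
        value, gE = llgi(self.refl, sf, self.sigma_a_bins, mask=self.res_mask)
        g_amp = normalized_amplitude_vjp(np.abs(sf.F_c), self.refl.epsilon,
                                         self.refl.bin_id, gE)
        gF = amplitude_cotangent(sf.F_c, g_amp)
        gx, gb = self.calc.vjp(gF)
        return value, gx, gb

    def llg(self, xyz, b_iso) -> float:
        return self.loss_and_gradients(xyz, b_iso)[0]
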