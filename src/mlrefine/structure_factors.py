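"""Direct-summation structure factors with analytic derivatives.

F(h) = sum_atoms occ * f_elem(s) * exp(-B s^2 / 4) * exp(2 pi i h . x_frac)

The same machinery serves the crystallographic target (F at observed hkl)
and the cryo-EM target (Fourier terms of the model density on the map box,
which is a P1 cell). Derivatives with respect to Cartesian coordinates and
isotropic B factors are closed-form; gradients of any scalar loss are pulled
back with vector-Jacobian products rather than materializing full Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AtomicModel
from .reciprocal import ReflectionSet, UnitCell

# 4-Gaussian + constant X-ray form factors (International Tables vol. C,
# 6.1.1.4) for the elements of a protein backbone; argument is (s/2)^2.
IT92 = {
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "S": ([6.90530, 5.20340, 1.43790, 1.58630],
          [1.46790, 22.2151, 0.253600, 56.1720], 0.866900),
}
_Z = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "SE": 34, "FE": 26,
      "MG": 12, "ZN": 30, "CA": 20, "MN": 25, "K": 19, "NA": 11, "CL": 17}


def form_factor(element: str, s: np.ndarray) -> np.ndarray:
    """X-ray scattering factor at reciprocal resolution s = 1/d.

    C, N, O, S use tabulated 4-Gaussian coefficients; other known elements
    fall back to carbon's shape scaled by atomic number. Hydrogens scatter
    weakly and are ignored upstream.
    """
    elem = element.upper()
    if elem == "H":
        return np.zeros_like(np.asarray(s, dtype=float))
    if elem in IT92:
        a, b, c = IT92[elem]
        scale = 1.0
    elif elem in _Z:
        a, b, c = IT92["C"]
        scale = _Z[elem] / 6.0
    else:
        raise ValueError(f"unknown element symbol: {element!r}")
    q2 = (np.asarray(s, dtype=float) / 2.0) ** 2
    f = c + sum(ai * np.exp(-bi * q2) for ai, bi in zip(a, b))
    return scale * f


@dataclass
class ModelStructureFactors:
    F_c: np.ndarray               # complex
    E_C: np.ndarray | None = None
    phi_calc: np.ndarray | None = None

    def __post_init__(self):
        if self.phi_calc is None:
            self.phi_calc = np.angle(self.F_c)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.F_c)


class DirectSummation:
    """Structure factors of a model at a fixed set of Miller/Fourier indices,
    with vector-Jacobian products for coordinates and B factors.

    Reuse one instance per (hkl set, cell); call :meth:`compute` with fresh
    coordinates at every pose or iteration.
    """

    def __init__(self, cell: UnitCell, hkl: np.ndarray, s: np.ndarray,
                 elements: np.ndarray, occupancy: np.ndarray, ops=None):
        self.cell = cell
        self.hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        self.s = np.asarray(s, dtype=float)
        keep = np.array([e.upper() != "H" for e in elements])
        self._keep = keep
        self.occ = np.asarray(occupancy, dtype=float)[keep]
        self.f0 = np.stack(
            [form_factor(e, self.s) for e in np.asarray(elements)[keep]],
            axis=1,
        )  # (n_refl, n_atoms)
        # rows of frac are reciprocal basis vectors; h.x_frac = (hkl@frac).x
        self._hfrac = self.hkl @ cell.frac  # (n_refl, 3), = 1/d vectors
        # symmetry expansion: Cartesian linear map and shift of each operator
        if ops is None:
            self._sym = [(np.eye(3), np.zeros(3))]
        else:
            self._sym = [
                (cell.orth @ rot @ cell.frac, cell.orth @ tran)
                for rot, tran in zip(ops.rotations, ops.translations)
            ]
        self._cache = None

    def compute(self, xyz: np.ndarray, b_iso: np.ndarray) -> np.ndarray:
        """Complex F at every index; caches per-atom terms for backprop.

        Symmetry mates of each atom are generated through the operators'
        Cartesian maps, so the sum covers the whole P1 content while the
        caller only ever supplies (and receives gradients for) the unique
        copy.
        """
        xyz = np.asarray(xyz, dtype=float)[self._keep]
        if np.isnan(xyz).any():
            raise ValueError("NaN coordinate")
        b = np.asarray(b_iso, dtype=float)[self._keep]
        # the B-dependent prefactor is stable across pose searches; cache it
        key = b.tobytes()
        if getattr(self, "_prefac_key", None) != key:
            debye = np.exp(-b[None, :] * (self.s[:, None] ** 2) / 4.0)
            self._prefac = self.occ[None, :] * self.f0 * debye
            self._prefac_key = key
        prefac = self._prefac
        F = np.zeros(len(self.hkl), dtype=complex)
        term_list = []
        for mat, shift in self._sym:
            xk = xyz @ mat.T + shift
            phase = 2.0 * np.pi * (self._hfrac @ xk.T)      # (n_refl, n_atoms)
            terms = prefac * np.exp(1j * phase)
            F += terms.sum(axis=1)
            term_list.append(terms)
        self._cache = (xyz, b, term_list)
        return F

    def vjp(self, gF: np.ndarray):
        """Pull a cotangent on F back to (d/dxyz, d/db_iso).

        ``gF`` is complex with gF = dL/dRe(F) + i dL/dIm(F); the returned
        arrays cover all atoms of the original model (zeros for skipped H),
        with symmetry-mate contributions folded back through each
        operator's linear map.
        """
        if self._cache is None:
            raise RuntimeError("call compute() before vjp()")
        xyz, b, term_list = self._cache
        n_kept = len(xyz)
        gx_kept = np.zeros((n_kept, 3))
        gb_kept = np.zeros(n_kept)
        for (mat, _shift), terms in zip(self._sym, term_list):
            # dF/dx_cart,j = terms_j * 2 pi i * (hfrac @ mat) per reflection
            w = np.conj(gF)[:, None] * terms                 # (n_refl, n_atoms)
            gxk = 2.0 * np.pi * np.einsum(
                "ra,rd->ad", np.real(1j * w), self._hfrac @ mat
            )
            gx_kept += gxk
            gb_kept += np.einsum("ra,r->a", np.real(w), -self.s ** 2 / 4.0)
        n_total = len(self._keep)
        gx = np.zeros((n_total, 3))
        gb = np.zeros(n_total)
        gx[self._keep] = gx_kept
        gb[self._keep] = gb_kept
        return gx, gb


def direct_sum_structure_factors(model: AtomicModel, cell: UnitCell,
                                 refl: ReflectionSet,
                                 ops=None) -> ModelStructureFactors:
    """One-shot structure-factor calculation at the reflection set's indices."""
    calc = DirectSummation(cell, refl.hkl, refl.s, model.elements,
                           model.occupancy, ops=ops)
    F = calc.compute(model.xyz, model.b_iso)
    return ModelStructureFactors(F_c=F)


def amplitude_cotangent(F: np.ndarray, g_amp: np.ndarray,
                        g_phase: np.ndarray | None = None) -> np.ndarray:
    """Convert cotangents on |F| (and optionally arg F) to a cotangent on F."""
    amp = np.abs(F)
    safe = np.where(amp > 0, amp, 1.0)
    gF = g_amp * F / safe
    if g_phase is not None:
        gF = gF + g_phase * 1j * F / safe ** 2
    return gF


def normalized_amplitude_vjp(amp: np.ndarray, epsilon: np.ndarray,
                             bin_id: np.ndarray, gE: np.ndarray) -> np.ndarray:
    """Exact backward pass through binned Wilson normalization.

    E_h = amp_h / sqrt(eps_h S_b), S_b = <amp^2/eps>_bin. The bin scale S_b
    depends on every amplitude in the bin, so the pullback has a diagonal
    term plus a rank-one bin correction.
    """
    g_amp = np.zeros_like(amp)
    for b in np.unique(bin_id):
        sel = bin_id == b
        a = amp[sel]
        eps = epsilon[sel]
        g = gE[sel]
        S = np.mean(a ** 2 / eps)
        inner = np.sum(g * a / np.sqrt(eps))
        g_amp[sel] = (g / np.sqrt(eps * S)
                      - (a / eps) * inner / (len(a) * S ** 1.5))
    return g_amp
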