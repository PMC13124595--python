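"""Confidence conversions: pLDDT -> pseudo-B -> alignment weight."""

from __future__ import annotations

import numpy as np

_PSEUDOB_PREFACTOR = 8.0 * np.pi ** 2 / 3.0


def plddt_to_pseudob(plddt):
    """Pseudo isotropic B factor (A^2) from predicted confidence.

    pLDDT is first converted to an equivalent positional r.m.s.d.
    1.5 * exp(4 * (0.7 - 0.01 * pLDDT)) and then to an isotropic B via
    B = (8 pi^2 / 3) * rmsd^2. Strictly decreasing in pLDDT.
    """
    plddt = np.asarray(plddt, dtype=float)
    if np.any(plddt < 0) or np.any(plddt > 100):
        raise ValueError("pLDDT must lie in [0, 100]")
    rmsd = 1.5 * np.exp(4.0 * (0.7 - 0.01 * plddt))
    return _PSEUDOB_PREFACTOR * rmsd ** 2


def pseudob_derivative(plddt):
    """d(pseudo-B)/d(pLDDT); the chain-rule factor for confidence-driven
    gradients."""
    plddt = np.asarray(plddt, dtype=float)
    return plddt_to_pseudob(plddt) * (-0.08)


def kabsch_weight(pseudo_b):
    """Empirical alignment weight from pseudo-B: full weight for confident
    residues, a linear ramp to 0.5 on (11.5, 40], then an exponential decay.
    Continuous at both breakpoints."""
    b = np.asarray(pseudo_b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("pseudo-B must be positive")
    ramp = 1.0 - 0.5 * (b - 11.5) / (40.0 - 11.5)
    tail = 0.5 * np.exp(-np.sqrt(np.maximum(b - 40.0, 0.0)))
    return np.where(b <= 11.5, 1.0, np.where(b <= 40.0, ramp, tail))
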