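"""Atomic model container shared by all targets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AtomicModel:
    """A single-chain atomic model with per-atom and per-residue annotations.

    Coordinates are Cartesian angstroms. ``resid`` maps each atom to a
    0-based residue index; per-residue arrays (``plddt``, anything derived
    from it) are indexed by that value.
    """

    xyz: np.ndarray              # (n_atoms, 3) float
    elements: np.ndarray         # (n_atoms,) str, e.g. "C", "N"
    occupancy: np.ndarray        # (n_atoms,) float in (0, 1]
    b_iso: np.ndarray            # (n_atoms,) float >= 0, A^2
    resid: np.ndarray            # (n_atoms,) int residue index
    atom_names: np.ndarray       # (n_atoms,) str, e.g. "CA"
    plddt: np.ndarray | None = None   # (n_residues,) float in [0, 100]
    chain: str = "A"
    resnames: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n_atoms, 3)")
        if np.isnan(self.xyz).any():
            raise ValueError("NaN coordinate in model")
        n = len(self.xyz)
        for name in ("elements", "occupancy", "b_iso", "resid", "atom_names"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_atoms {n}")
            setattr(self, name, arr)
        if np.any(self.occupancy <= 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancy must be in (0, 1]")
        if np.any(self.b_iso < 0):
            raise ValueError("b_iso must be >= 0")
        if self.resnames is None:
            self.resnames = np.array(["ALA"] * n)

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    @property
    def n_residues(self) -> int:
        return int(self.resid.max()) + 1 if self.n_atoms else 0

    @property
    def ca_mask(self) -> np.ndarray:
        return self.atom_names == "CA"

    @property
    def ca_xyz(self) -> np.ndarray:
        return self.xyz[self.ca_mask]

    def with_xyz(self, xyz: np.ndarray) -> "AtomicModel":
        return replace(self, xyz=np.asarray(xyz, dtype=float))

    def with_b_iso(self, b_iso: np.ndarray) -> "AtomicModel":
        return replace(self, b_iso=np.asarray(b_iso, dtype=float))

    def residue_to_atom(self, per_residue: np.ndarray) -> np.ndarray:
        """Broadcast a per-residue array onto atoms."""
        per_residue = np.asarray(per_residue)
        return per_residue[self.resid]

    def copy(self) -> "AtomicModel":
        return replace(self, xyz=self.xyz.copy(), b_iso=self.b_iso.copy())
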