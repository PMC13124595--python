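"""File-format adapters (gemmi-backed) and run configuration."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .model import AtomicModel
from .reciprocal import (
    ReflectionSet,
    SpaceGroupOps,
    UnitCell,
    assign_bins,
    assign_free_flags,
    effective_amplitudes,
    reflection_metadata,
)


# -- coordinates -----------------------------------------------------------

def read_model(path) -> tuple[AtomicModel, UnitCell | None]:
    """Read PDB or mmCIF coordinates into an AtomicModel.

    Residues without a CA atom are kept but flagged with a warning (they are
    excluded from alignment sets by construction since alignment uses CA
    atoms only).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    xyz, elements, occ, b, resid, names, resnames = [], [], [], [], [], [], []
    chain_name = "A"
    res_index = -1
    for chain in model:
        chain_name = chain.name
        for res in chain:
            res_index += 1
            if not any(a.name == "CA" for a in res):
                warnings.warn(
                    f"residue {res.seqid.num} ({res.name}) has no CA; "
                    "excluded from alignment sets")
            for atom in res:
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
                occ.append(atom.occ)
                b.append(atom.b_iso)
                resid.append(res_index)
                names.append(atom.name)
                resnames.append(res.name)
        break  # single-chain scope
    am = AtomicModel(
        xyz=np.array(xyz), elements=np.array(elements),
        occupancy=np.array(occ), b_iso=np.array(b),
        resid=np.array(resid), atom_names=np.array(names),
        chain=chain_name, resnames=np.array(resnames),
    )
    cell = None
    if st.cell and st.cell.volume > 1.0:
        c = st.cell
        cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return am, cell


def write_model(model: AtomicModel, path, cell: UnitCell | None = None):
    """Write PDB (.pdb) or mmCIF (anything else)."""
    st = gemmi.Structure()
    st.name = "model"
    if cell is not None:
        st.cell = cell.to_gemmi()
        st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    ch = gemmi.Chain(model.chain)
    for res_index in np.unique(model.resid):
        res = gemmi.Residue()
        sel = model.resid == res_index
        res.name = str(model.resnames[sel][0])
        res.seqid = gemmi.SeqId(int(res_index) + 1, " ")
        for i in np.flatnonzero(sel):
            atom = gemmi.Atom()
            atom.name = str(model.atom_names[i])
            atom.element = gemmi.Element(str(model.elements[i]))
            atom.pos = gemmi.Position(*model.xyz[i])
            atom.occ = float(model.occupancy[i])
            atom.b_iso = float(model.b_iso[i])
            res.add_atom(atom)
        ch.add_residue(res)
    md.add_chain(ch)
    st.add_model(md)
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# -- reflections -----------------------------------------------------------

DEFAULT_COLUMNS = {
    "intensity": "intensity_meas",
    "sigma": "intensity_sigma",
    "e_effective": "pdbx_E_effective",
    "d_obs": "pdbx_D_obs",
    "free": "status",
}


def read_reflections(path, columns: dict | None = None,
                     n_bins: int = 20, free_fraction: float = 0.05,
                     seed: int = 0):
    """Read MTZ or reflection CIF into a populated ReflectionSet.

    Column names are resolved through ``columns`` (merged over sensible
    defaults). Precomputed E_e/D_obs/free columns are honored verbatim when
    present; otherwise E_e and D_obs are derived from intensities and free
    flags are assigned randomly (seeded).
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    path = Path(path)
    if path.suffix.lower() == ".mtz":
        return _read_mtz(path, cols, n_bins, free_fraction, seed)
    return _read_refln_cif(path, cols, n_bins, free_fraction, seed)


def _finalize(refl, I, sigma, e_e, d_obs, free, cols, n_bins,
              free_fraction, seed):
    if sigma is None:
        raise ValueError(
            f"missing sigma column (column map: {cols})")
    refl.I_o = I
    refl.sigma_I = sigma
    assign_bins(refl, n_bins=n_bins)
    if free is not None:
        refl.free_flag = free
    else:
        assign_free_flags(refl, fraction=free_fraction, seed=seed)
    if e_e is not None and d_obs is not None:
        refl.E_e = e_e
        refl.D_obs = d_obs
    else:
        effective_amplitudes(refl.I_o, refl.sigma_I, refl)
    return refl


def _read_mtz(path, cols, n_bins, free_fraction, seed):
    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c,
                    mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    ops = SpaceGroupOps(mtz.spacegroup.xhm())
    data = np.array(mtz, copy=True)
    labels = [c.label for c in mtz.columns]

    def col(name):
        return data[:, labels.index(name)] if name in labels else None

    hkl = data[:, :3].astype(int)
    refl = reflection_metadata(cell, ops, hkl)
    free = col(cols["free"])
    if free is not None:
        free = free.astype(int) == 0
    return _finalize(refl, col(cols["intensity"]), col(cols["sigma"]),
                     col(cols["e_effective"]), col(cols["d_obs"]), free,
                     cols, n_bins, free_fraction, seed), cell


def _read_refln_cif(path, cols, n_bins, free_fraction, seed):
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cell = UnitCell(
        *[float(block.find_value(f"_cell.length_{x}")) for x in "abc"],
        *[float(block.find_value(f"_cell.angle_{x}"))
          for x in ("alpha", "beta", "gamma")],
    )
    sg = block.find_value("_symmetry.space_group_name_H-M") or "P 1"
    ops = SpaceGroupOps(sg.strip("'\""))

    def loop(tag, dtype=float, required=False):
        col_ = block.find_loop(f"_refln.{tag}")
        if not col_:
            if required:
                raise ValueError(f"missing column _refln.{tag} "
                                 f"(column map: {cols})")
            return None
        vals = list(col_)
        if dtype is float:
            bad = [i for i, v in enumerate(vals) if v in ("?", ".")]
            if bad:
                raise ValueError(
                    f"malformed value in _refln.{tag} at row {bad[0] + 1}")
            return np.array(vals, dtype=float)
        return np.array(vals)

    hkl = np.stack([loop("index_h", required=True),
                    loop("index_k", required=True),
                    loop("index_l", required=True)], axis=1).astype(int)
    refl = reflection_metadata(cell, ops, hkl)
    free_raw = loop(cols["free"], dtype=str)
    free = None
    if free_raw is not None:
        free = np.array([v in ("f", "F", "1") for v in free_raw])
    return _finalize(refl, loop(cols["intensity"], required=True),
                     loop(cols["sigma"]),
                     loop(cols["e_effective"]), loop(cols["d_obs"]), free,
                     cols, n_bins, free_fraction, seed), cell


def write_reflections_cif(refl: ReflectionSet, cell: UnitCell, path,
                          spacegroup: str = "P 1"):
    """Textual reflection CIF with intensities, sigmas and free flags."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    for tag, x in zip("abc", (cell.a, cell.b, cell.c)):
        block.set_pair(f"_cell.length_{tag}", f"{x:.4f}")
    for tag, x in zip(("alpha", "beta", "gamma"),
                      (cell.alpha, cell.beta, cell.gamma)):
        block.set_pair(f"_cell.angle_{tag}", f"{x:.3f}")
    block.set_pair("_symmetry.space_group_name_H-M", f"'{spacegroup}'")
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                       "intensity_meas", "intensity_sigma",
                                       "status"])
    for i in range(len(refl)):
        flag = "f" if (refl.free_flag is not None
                       and refl.free_flag[i]) else "o"
        loop.add_row([str(refl.hkl[i, 0]), str(refl.hkl[i, 1]),
                      str(refl.hkl[i, 2]), f"{refl.I_o[i]:.6g}",
                      f"{refl.sigma_I[i]:.6g}", flag])
    doc.write_file(str(path))


# -- maps ------------------------------------------------------------------

def write_map(grid: np.ndarray, cell: UnitCell, path):
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid, dtype=np.float32))
    m.grid.unit_cell = cell.to_gemmi()
    m.grid.spacegroup = gemmi.SpaceGroup("P 1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_map(path) -> tuple[np.ndarray, UnitCell]:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))  # normalizes axis order to X,Y,Z
    grid = np.array(m.grid, copy=True)
    c = m.grid.unit_cell
    return grid, UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)


# -- profiles and config ---------------------------------------------------

def write_profile(path, **arrays):
    np.savez(path, **arrays)


def read_profile(path):
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


@dataclass
class RunConfig:
    """Serializable run configuration; round-trips losslessly via YAML."""

    lr_mul: float = 1.0
    lr_add: float = 0.05
    omega_l2: float = 1e-11
    n_iter_phase1: int = 100
    n_traces: int = 3
    lr_mul_phase2: float = 1e-3
    lr_add_phase2: float = 1e-3
    n_iter_phase2: int = 500
    early_stop_window: int = 50
    early_stop_threshold: float = 0.1
    phase1_d_min: float = 3.0
    seed: int = 0
    output_dir: str = "."
    columns: dict = field(default_factory=dict)
    verbosity: int = 1

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def engine_config(self):
        from .engine import RefinementConfig
        keys = {f for f in RefinementConfig.__dataclass_fields__}
        return RefinementConfig(**{k: v for k, v in asdict(self).items()
                                   if k in keys})
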