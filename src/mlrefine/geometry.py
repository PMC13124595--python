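"""Ideal-geometry backbone construction from torsion angles.

Builds a polyalanine-like N-CA-C-O backbone with fixed bond lengths and
angles; the conformation is controlled entirely by the (phi, psi) torsion
lists. The analytic Jacobian of every atom position with respect to every
torsion is available in closed form (rotation of downstream atoms about the
torsion's bond axis), which is what makes the toy structure predictor exactly
differentiable.
"""

from __future__ import annotations

import numpy as np

# Engh & Huber-style ideal backbone parameters (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_rad: float):
    """NeRF placement of atom d given positions a-b-c, the c-d bond length,
    the b-c-d angle and the a-b-c-d torsion."""
    angle = np.deg2rad(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion_rad),
            bond * np.sin(angle) * np.sin(torsion_rad),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray):
    """Build an N/CA/C/O backbone chain from torsions.

    ``phi[0]`` is unused (no preceding carbonyl); both arrays have length
    n_residues. Returns (coords, atom_names, resid, elements, torsion_info)
    where torsion_info is the bookkeeping needed by
    :func:`backbone_torsion_jacobian`: a list of
    (kind, residue, axis_b_index, axis_c_index, first_dependent_atom_extra).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same length")
    n_res = len(phi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")

    coords = []
    names = []
    resid = []
    elements = []
    index = {}

    def add(name, res, elem, pos):
        index[(res, name)] = len(coords)
        coords.append(pos)
        names.append(name)
        resid.append(res)
        elements.append(elem)

    # first residue seeded in a canonical frame
    add("N", 0, "N", np.array([0.0, 0.0, 0.0]))
    add("CA", 0, "C", np.array([BOND_N_CA, 0.0, 0.0]))
    ang = np.deg2rad(ANGLE_N_CA_C)
    add(
        "C",
        0,
        "C",
        coords[1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]),
    )

    torsions = []  # (kind, res, b_idx, c_idx)

    for i in range(n_res):
        n_i = index[(i, "N")]
        ca_i = index[(i, "CA")]
        c_i = index[(i, "C")]
        # carbonyl O: torsion psi_i + pi about the CA-C axis
        o_pos = place_atom(
            coords[n_i], coords[ca_i], coords[c_i], BOND_C_O, ANGLE_CA_C_O,
            psi[i] + np.pi,
        )
        add("O", i, "O", o_pos)
        if i == n_res - 1:
            torsions.append(("psi", i, ca_i, c_i))
            break
        # next N via psi_i
        nn = place_atom(
            coords[n_i], coords[ca_i], coords[c_i], BOND_C_N, ANGLE_CA_C_N,
            psi[i],
        )
        add("N", i + 1, "N", nn)
        torsions.append(("psi", i, ca_i, c_i))
        # next CA via omega (fixed)
        nca = place_atom(
            coords[ca_i], coords[c_i], nn, BOND_N_CA, ANGLE_C_N_CA,
            np.deg2rad(OMEGA),
        )
        add("CA", i + 1, "C", nca)
        # next C via phi_{i+1}
        nc = place_atom(
            coords[c_i], nn, nca, BOND_CA_C, ANGLE_N_CA_C, phi[i + 1]
        )
        add("C", i + 1, "C", nc)
        torsions.append(("phi", i + 1, index[(i + 1, "N")], index[(i + 1, "CA")]))

    coords = np.array(coords)
    info = {
        "torsions": torsions,
        "index": index,
        "names": np.array(names),
        "resid": np.array(resid),
        "elements": np.array(elements),
    }
    return coords, info


def backbone_torsion_jacobian(coords: np.ndarray, info: dict) -> np.ndarray:
    """Closed-form d(coords)/d(torsion) for every torsion in build order.

    Changing a torsion rotates every atom placed after its axis atom ``c``
    about the axis through ``c`` along (c - b):
    dx_j/dtheta = u x (x_j - x_c). The carbonyl O of residue i shares the
    psi_i parameter, which the "placed after c" rule captures because O is
    added immediately after C.

    Returns (n_torsions, n_atoms, 3); torsion order matches
    ``info["torsions"]``.
    """
    torsions = info["torsions"]
    n_atoms = len(coords)
    jac = np.zeros((len(torsions), n_atoms, 3))
    for k, (_kind, _res, b_idx, c_idx) in enumerate(torsions):
        u = coords[c_idx] - coords[b_idx]
        u = u / np.linalg.norm(u)
        dependent = np.arange(n_atoms) > c_idx
        rel = coords[dependent] - coords[c_idx]
        jac[k, dependent] = np.cross(u, rel)
    return jac


def torsion_order(info: dict):
    """(kind, residue) labels matching the Jacobian's first axis."""
    return [(kind, res) for kind, res, _, _ in info["torsions"]]
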