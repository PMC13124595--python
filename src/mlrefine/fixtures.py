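"""Synthetic inputs for every target: toy structures, simulated reflection
data, simulated half-maps and cluster profiles with planted couplings.

Everything is generated from a seeded :class:`FixtureRecipe`, so all
fixtures are bit-reproducible and no external data is ever required. The
"truth" structure factors reuse the production direct-summation code path;
the test suite guards that path with an independent plain-loop oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import build_backbone
from .model import AtomicModel
from .cryoem_target import model_map
from .reciprocal import (
    ReflectionSet,
    SpaceGroupOps,
    UnitCell,
    assign_bins,
    assign_free_flags,
    effective_amplitudes,
    reflection_metadata,
)
from .structure_factors import DirectSummation


@dataclass
class FixtureRecipe:
    """All knobs of the synthetic data generator, with study defaults."""

    n_residues: int = 10
    loop_start: int = 4                   # residues whose torsions differ
    loop_len: int = 3
    loop_delta_deg: float = 35.0          # state A -> B torsion change
    helix_phi_deg: float = -60.0
    helix_psi_deg: float = -45.0
    cell_padding: float = 7.0             # A of empty space around the chain
    d_min: float = 3.0                    # reflection resolution limit
    intensity_frac_error: float = 0.05    # sigma_I = frac*I + floor
    intensity_floor_frac: float = 0.01    # floor, fraction of mean intensity
    free_fraction: float = 0.05
    n_bins: int = 8
    map_shape: tuple = (32, 32, 32)
    map_noise_to_signal: float = 0.25     # per-shell noise/signal power
    n_clusters: int = 12
    n_profile_channels: int = 23
    profile_concentration: float = 0.8    # Dirichlet sharpness of columns
    spacegroup: str = "P 1"
    seed: int = 0


def _torsions(recipe: FixtureRecipe, state: str):
    phi = np.full(recipe.n_residues, np.deg2rad(recipe.helix_phi_deg))
    psi = np.full(recipe.n_residues, np.deg2rad(recipe.helix_psi_deg))
    if state == "B":
        lo = recipe.loop_start
        hi = lo + recipe.loop_len
        delta = np.deg2rad(recipe.loop_delta_deg)
        phi[lo:hi] += delta
        psi[lo:hi] -= delta
    elif state != "A":
        raise ValueError("state must be 'A' or 'B'")
    return phi, psi


def make_toy_structure(recipe: FixtureRecipe, state: str = "A",
                       b_iso: float = 15.0) -> AtomicModel:
    """Ideal-geometry backbone in conformation 'A' (baseline) or 'B'
    (loop-perturbed)."""
    if recipe.n_residues < 5:
        raise ValueError("need at least 5 residues")
    phi, psi = _torsions(recipe, state)
    xyz, info = build_backbone(phi, psi)
    n = len(xyz)
    return AtomicModel(
        xyz=xyz,
        elements=info["elements"],
        occupancy=np.ones(n),
        b_iso=np.full(n, float(b_iso)),
        resid=info["resid"],
        atom_names=info["names"],
    )


def bounding_cell(models, padding: float) -> UnitCell:
    """Orthorhombic P1 cell enclosing one or more models with uniform
    padding, shifting all of them (in place) by one common offset so that
    they stay in a single consistent frame."""
    if isinstance(models, AtomicModel):
        models = [models]
    allxyz = np.vstack([m.xyz for m in models])
    span = allxyz.max(axis=0) - allxyz.min(axis=0)
    offset = -allxyz.min(axis=0) + padding
    for m in models:
        m.xyz = m.xyz + offset
    return UnitCell(*np.round(span + 2.0 * padding, 3))


def toy_system(recipe: FixtureRecipe, b_iso: float = 15.0):
    """Both conformations in one shared P1 cell.

    Returns (state_a, state_b, cell); data simulated from one state can be
    refined starting from the other without any further alignment.
    """
    a = make_toy_structure(recipe, "A", b_iso=b_iso)
    b = make_toy_structure(recipe, "B", b_iso=b_iso)
    cell = bounding_cell([a, b], recipe.cell_padding)
    return a, b, cell


def full_hkl_sphere(cell: UnitCell, d_min: float) -> np.ndarray:
    """Unique-hemisphere integer indices to the resolution limit."""
    hmax = int(np.floor(cell.a / d_min))
    kmax = int(np.floor(cell.b / d_min))
    lmax = int(np.floor(cell.c / d_min))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(0, lmax + 1), indexing="ij")
    hkl = np.stack([h, k, l], axis=-1).reshape(-1, 3)
    # hemisphere: l > 0, or l == 0 and (k > 0 or (k == 0 and h > 0))
    keep = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & ((hkl[:, 1] > 0)
            | ((hkl[:, 1] == 0) & (hkl[:, 0] > 0))))
    hkl = hkl[keep]
    s = cell.s(hkl)
    return hkl[(s > 0) & (s <= 1.0 / d_min)]


def simulate_reflections(model: AtomicModel, recipe: FixtureRecipe,
                         cell: UnitCell | None = None):
    """Reflection data with Gaussian intensity noise from a truth model.

    Returns (refl, cell, F_true). I_o = |F|^2 + N(0, sigma_I) with
    sigma_I = frac*|F|^2 + floor; bins, free flags, E_e and D_obs are
    populated.
    """
    if 1.0 / recipe.d_min > 1.0 / 1.5:
        raise ValueError("resolution limit must be 1.5 A or coarser")
    if cell is None:
        model = model.copy()
        cell = bounding_cell(model, recipe.cell_padding)
    rng = np.random.default_rng(recipe.seed)
    hkl = full_hkl_sphere(cell, recipe.d_min)
    ops = SpaceGroupOps(recipe.spacegroup)
    refl = reflection_metadata(cell, ops, hkl)
    calc = DirectSummation(cell, refl.hkl, refl.s, model.elements,
                           model.occupancy, ops=ops)
    F_true = calc.compute(model.xyz, model.b_iso)
    I_true = np.abs(F_true) ** 2
    sigma_I = (recipe.intensity_frac_error * I_true
               + recipe.intensity_floor_frac * I_true.mean())
    refl.I_o = I_true + rng.normal(0.0, sigma_I)
    refl.sigma_I = sigma_I
    assign_bins(refl, n_bins=recipe.n_bins, min_per_bin=20)
    assign_free_flags(refl, fraction=recipe.free_fraction, seed=recipe.seed)
    effective_amplitudes(refl.I_o, refl.sigma_I, refl)
    return refl, cell, F_true


def simulate_half_maps(model: AtomicModel, recipe: FixtureRecipe,
                       cell: UnitCell | None = None):
    """Two half-maps: model density plus independent shell-scaled noise.

    Noise in each half-map has per-shell power equal to
    ``map_noise_to_signal`` times the shell's mean signal power. Returns
    (map1, map2, cell, clean_map).
    """
    from .map_simulation import grid_frequencies, make_shells

    if cell is None:
        model = model.copy()
        cell = bounding_cell(model, recipe.cell_padding)
    shape = tuple(recipe.map_shape)
    clean = model_map(model, cell, shape, d_min=recipe.d_min)
    rng = np.random.default_rng(recipe.seed + 1)
    F = np.fft.rfftn(clean)
    _, s = grid_frequencies(shape, cell)
    shell_id, _ = make_shells(s, min_terms=50)
    pw_floor = 1e-12 * float(np.abs(F).max()) ** 2
    maps = []
    for half in range(2):
        noise = np.fft.rfftn(rng.standard_normal(shape))
        Fn = F.copy()
        for b in range(int(shell_id.max()) + 1):
            sel = shell_id == b
            sig_pw = float(np.mean(np.abs(F[sel]) ** 2))
            noise_pw = float(np.mean(np.abs(noise[sel]) ** 2))
            if sig_pw <= pw_floor:
                # beyond the band limit: keep the shell exactly empty
                Fn[sel] = 0.0
            elif noise_pw > 0:
                Fn[sel] += noise[sel] * np.sqrt(
                    recipe.map_noise_to_signal * sig_pw / noise_pw)
        maps.append(np.fft.irfftn(Fn, s=shape))
    return maps[0], maps[1], cell, clean


def simulate_profiles(recipe: FixtureRecipe,
                      planted_pairs: list | None = None):
    """(m_init, m_final) cluster profiles; m_final carries planted
    pairwise couplings that dominate the dMI ranking.

    m_init columns are independent Dirichlet draws shared across clusters
    with per-cluster noise. For each planted pair (i, j), m_final rewrites
    both columns cluster-by-cluster as near-one-hot vectors at a shared,
    cluster-specific symbol, creating a strong joint dependence.
    """
    if recipe.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    rng = np.random.default_rng(recipe.seed + 2)
    k, n, c = (recipe.n_clusters, recipe.n_residues,
               recipe.n_profile_channels)
    base = rng.dirichlet(np.full(c, recipe.profile_concentration), size=n)
    jitter = rng.dirichlet(np.full(c, 5.0), size=(k, n))
    m_init = 0.8 * base[None, :, :] + 0.2 * jitter
    m_final = m_init.copy()
    if planted_pairs:
        for i, j in planted_pairs:
            symbols = rng.integers(0, c, size=k)
            for kk in range(k):
                col = np.full(c, 0.01 / (c - 1))
                col[symbols[kk]] = 0.99
                m_final[kk, i, :] = col
                m_final[kk, j, :] = col
    return m_init, m_final
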