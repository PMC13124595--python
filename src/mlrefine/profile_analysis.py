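"""Mutual-information analysis of MSA cluster profiles.

Treats each cluster as an equally-weighted soft sample over symbol
distributions: after per-cluster column renormalization, the joint symbol
distribution of residues (i, j) is the cluster average of the outer product
of their columns. The resulting residue-residue MI matrix, its change
between an initial and an optimized profile, and progressive muting of the
highest-|dMI| residues quantify which pairwise coevolutionary signals an
optimization rewired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class MIMatrix:
    """Symmetric residue-residue mutual information (nats)."""

    values: np.ndarray
    normalization: str = "raw"

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def normalized(self) -> "MIMatrix":
        """Min-max rescaling of off-diagonal values to [0, 1]."""
        v = self.values.copy()
        off = ~np.eye(len(v), dtype=bool)
        lo, hi = v[off].min(), v[off].max()
        if hi > lo:
            v = (v - lo) / (hi - lo)
            v[~off] = 0.0
        return MIMatrix(values=v, normalization="minmax")


def _column_normalize(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 3:
        raise ValueError("profile must be (clusters, residues, channels)")
    if np.any(m < 0):
        raise ValueError("profile values must be non-negative")
    sums = m.sum(axis=2, keepdims=True)
    bad = np.nonzero((sums == 0).any(axis=0).ravel())[0]
    if bad.size:
        raise ValueError(f"all-zero profile column at residue {bad[0]}")
    return m / sums


def profile_mi(m: np.ndarray) -> MIMatrix:
    """Residue-residue MI from a cluster profile.

    joint p_ij(a,b) = mean_k mhat[k,i,a] * mhat[k,j,b] with per-cluster
    column renormalization; marginals are the cluster-mean columns, which
    are exactly the joint's marginals, so MI >= 0. The diagonal is zeroed
    by convention.
    """
    mhat = _column_normalize(m)
    k, n, c = mhat.shape
    if k < 2:
        raise ValueError("need at least 2 clusters")
    marg = mhat.mean(axis=0)                      # (n, c)
    # joint over all pairs at once: (i, j, a, b)
    joint = np.einsum("kia,kjb->ijab", mhat, mhat) / k
    denom = marg[:, None, :, None] * marg[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(joint > 0, np.log(joint / np.maximum(denom, 1e-300)),
                            0.0)
    mi = np.einsum("ijab,ijab->ij", joint, logratio)
    mi = 0.5 * (mi + mi.T)
    np.fill_diagonal(mi, 0.0)
    mi = np.maximum(mi, 0.0)
    return MIMatrix(values=mi)


def delta_mi_ranking(mi_init: MIMatrix, mi_final: MIMatrix, top_n: int):
    """Residue pairs ranked by |dMI| (descending, lexicographic ties).

    Returns (pairs, unique_residues, degree) where degree[r] counts r's
    appearances among the top_n pairs.
    """
    a = mi_init.values
    b = mi_final.values
    if a.shape != b.shape:
        raise ValueError("MI matrices must have the same shape")
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    delta = np.abs(b[iu, ju] - a[iu, ju])
    order = np.lexsort((ju, iu, -delta))
    pairs = [(int(iu[o]), int(ju[o]), float(delta[o])) for o in order]
    top = pairs[:top_n]
    degree = np.zeros(n, dtype=int)
    for i, j, _ in top:
        degree[i] += 1
        degree[j] += 1
    unique = sorted({r for i, j, _ in top for r in (i, j)})
    return pairs, unique, degree


def mute_profile(m_final: np.ndarray, m_init: np.ndarray,
                 residues) -> np.ndarray:
    """Restore selected residues' profile columns (all clusters, all
    channels) to their initial values."""
    m_final = np.asarray(m_final, dtype=float)
    m_init = np.asarray(m_init, dtype=float)
    if m_final.shape != m_init.shape:
        raise ValueError("profiles must have the same shape")
    residues = list(residues)
    if len(set(residues)) != len(residues):
        warnings.warn("duplicate residue indices collapsed")
        residues = sorted(set(residues))
    out = m_final.copy()
    out[:, residues, :] = m_init[:, residues, :]
    return out


def muting_baselines(m_final: np.ndarray, m_init: np.ndarray, k: int,
                     mode: str = "random", seed: int = 0) -> np.ndarray:
    """Mute k residues chosen by a baseline statistic.

    modes: 'random' (seeded uniform), 'entropy' (largest change in column
    entropy of the pooled profile), 'mean_abs_mi' (largest row mean of
    |dMI|).
    """
    n_res = m_final.shape[1]
    if k > n_res:
        raise ValueError("k exceeds the number of residues")
    if mode == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_res, size=k, replace=False)
    elif mode == "entropy":
        def col_entropy(m):
            p = _column_normalize(m).mean(axis=0)
            p = p / p.sum(axis=1, keepdims=True)
            return -np.sum(p * np.log(np.maximum(p, 1e-300)), axis=1)
        change = np.abs(col_entropy(m_final) - col_entropy(m_init))
        chosen = np.argsort(-change, kind="stable")[:k]
    elif mode == "mean_abs_mi":
        d = np.abs(profile_mi(m_final).values - profile_mi(m_init).values)
        chosen = np.argsort(-d.mean(axis=1), kind="stable")[:k]
    else:
        raise ValueError(f"unknown muting mode {mode!r}")
    return mute_profile(m_final, m_init, chosen)
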