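"""FSC modelling and half-map degradation to a target resolution.

The parametric FSC model
    FSC(s) = r / (r + exp(dB * s^2 / 4))
captures a half-map FSC curve with two numbers: r, the signal-to-noise power
ratio at zero scattering angle, and dB, the difference between the signal
and noise falloff B factors. Empirical laws fitted over the EMDB express
r and dB as functions of the nominal resolution cutoff s_max (where the
curve crosses the 0.143 criterion), so a single target resolution defines a
complete realistic FSC curve. Degradation adds independent complex Gaussian
noise to both half-maps, shell by shell, until their FSC matches that
target, then truncates beyond s_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

FSC_CRITERION = 0.143

# coefficients of the empirical r(s_max) and dB(s_max) laws
_R_COEF = (34.4680, 3.00533, 4.27895)
_DB_COEF = (17.1158, 12.0213, 21.3225)


@dataclass
class FSCModel:
    """Two-parameter FSC curve with its 0.143 crossing."""

    r: float                 # signal/noise power ratio at s = 0
    delta_b: float           # falloff difference (A^2)
    s_max: float | None = None  # 1/d where FSC = 0.143

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.s_max is None and self.delta_b > 0:
            self.s_max = self.criterion_crossing()

    def criterion_crossing(self, criterion: float = FSC_CRITERION):
        """s where the curve equals ``criterion`` (closed form)."""
        arg = self.r * (1.0 / criterion - 1.0)
        if arg <= 1.0 or self.delta_b <= 0:
            return None
        return float(np.sqrt(4.0 * np.log(arg) / self.delta_b))


def fsc_curve(model: FSCModel, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s must be non-negative")
    return model.r / (model.r + np.exp(model.delta_b * s ** 2 / 4.0))


def empirical_target(s_max: float) -> FSCModel:
    """FSC model for a desired resolution cutoff from the EMDB-fitted laws."""
    if not 0.05 < s_max < 0.7:
        raise ValueError(f"s_max {s_max} outside the fitted range (0.05, 0.7)")
    c0, c1, c2 = _R_COEF
    r = c0 * np.exp(c1 * s_max + c2 * s_max ** 2)
    d0, d1, d2 = _DB_COEF
    delta_b = d0 + d1 / s_max + d2 / s_max ** 2
    return FSCModel(r=float(r), delta_b=float(delta_b), s_max=float(s_max))


def fit_fsc_model(fsc: np.ndarray, s: np.ndarray) -> FSCModel:
    """Least-squares fit of the two-parameter curve to measured FSC values."""
    fsc = np.asarray(fsc, dtype=float)
    s = np.asarray(s, dtype=float)
    ok = (fsc > 0) & (fsc < 1)
    if ok.sum() < 5:
        raise ValueError("need at least 5 FSC points strictly inside (0,1)")
    fs, ss = fsc[ok], s[ok]

    def resid(p):
        model = FSCModel(r=np.exp(p[0]), delta_b=p[1], s_max=0.0)
        return fsc_curve(model, ss) - fs

    # initialize from the half-height point
    half = ss[np.argmin(np.abs(fs - 0.5))]
    db0 = 4.0 * np.log(100.0) / max(half, 1e-3) ** 2
    sol = least_squares(resid, x0=[np.log(100.0), db0],
                        bounds=([-5, 1e-6], [25, 1e5]))
    model = FSCModel(r=float(np.exp(sol.x[0])), delta_b=float(sol.x[1]),
                     s_max=None)
    if model.s_max is None:
        warnings.warn("fitted FSC curve never crosses 0.143; s_max undefined")
    return model


# ---------------------------------------------------------------------------
# Fourier-grid helpers shared with the cryo-EM target


def grid_frequencies(shape, cell) -> tuple[np.ndarray, np.ndarray]:
    """Integer frequencies and reciprocal resolution s for an rfftn layout.

    Returns (hkl, s) where hkl has shape (*rfft_shape, 3).
    """
    nx, ny, nz = shape
    fx = np.fft.fftfreq(nx, d=1.0 / nx).astype(int)
    fy = np.fft.fftfreq(ny, d=1.0 / ny).astype(int)
    fz = np.arange(nz // 2 + 1)
    h, k, l = np.meshgrid(fx, fy, fz, indexing="ij")
    hkl = np.stack([h, k, l], axis=-1)
    svec = hkl.reshape(-1, 3).astype(float) @ cell.frac
    s = np.linalg.norm(svec, axis=1).reshape(hkl.shape[:-1])
    return hkl, s


def make_shells(s: np.ndarray, n_shells: int | None = None,
                min_terms: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-in-s shells; returns (shell_id, shell_centers).

    Terms at s = 0 land in shell 0. The shell count is reduced until every
    shell holds at least ``min_terms`` terms.
    """
    s = np.asarray(s, dtype=float)
    smax = s.max()
    if n_shells is None:
        n_shells = max(3, int(np.sqrt(s.size / max(min_terms, 1))))
    edges = np.linspace(0.0, smax * (1 + 1e-9), n_shells + 1)
    shell_id = np.clip(np.digitize(s, edges) - 1, 0, n_shells - 1)
    # merge undersized shells (sparse innermost sphere, grid corners) into
    # their outward neighbor instead of coarsening every shell
    counts = np.bincount(shell_id.ravel(), minlength=n_shells)
    label = np.arange(n_shells)
    for b in range(n_shells - 1):
        if counts[b] < min_terms:
            counts[b + 1] += counts[b]
            counts[b] = 0
            label[label == b] = b + 1
    for b in range(n_shells - 1, 0, -1):
        if 0 < counts[b] < min_terms:
            keep = np.flatnonzero(counts[:b])
            tgt = keep[-1] if keep.size else b
            counts[tgt] += counts[b]
            counts[b] = 0
            label[label == b] = tgt
    uniq, relabel = np.unique(label, return_inverse=True)
    shell_id = relabel[shell_id]
    flat_s = s.ravel()
    flat_id = shell_id.ravel()
    centers = np.array([flat_s[flat_id == b].mean()
                        for b in range(len(uniq))])
    return shell_id, centers


def compute_fsc(F_1: np.ndarray, F_2: np.ndarray,
                shell_id: np.ndarray) -> np.ndarray:
    """Standard Fourier shell correlation per shell."""
    if F_1.shape != F_2.shape:
        raise ValueError("half-map Fourier arrays must share a grid")
    n_shells = int(shell_id.max()) + 1
    fsc = np.full(n_shells, np.nan)
    for b in range(n_shells):
        sel = shell_id == b
        if not sel.any():
            warnings.warn(f"empty FSC shell {b}; skipped")
            continue
        num = np.real(np.sum(F_1[sel] * np.conj(F_2[sel])))
        den = np.sqrt(np.sum(np.abs(F_1[sel]) ** 2)
                      * np.sum(np.abs(F_2[sel]) ** 2))
        fsc[b] = num / den if den > 0 else 0.0
    return fsc


def degrade_half_maps(map1: np.ndarray, map2: np.ndarray, cell,
                      target: FSCModel, seed: int,
                      n_shells: int | None = None, min_terms: int = 50):
    """Add shell-wise complex noise so the half-map FSC matches ``target``,
    then zero all Fourier terms beyond the target's s_max.

    Works on real-space half-map grids; returns (deg1, deg2, info) where
    info holds the shells, target and measured FSC values, and the seed.
    """
    if map1.shape != map2.shape:
        raise ValueError("half-maps must share a grid")
    rng = np.random.default_rng(seed)
    F1 = np.fft.rfftn(map1)
    F2 = np.fft.rfftn(map2)
    _, s = grid_frequencies(map1.shape, cell)
    shell_id, centers = make_shells(s, n_shells=n_shells,
                                    min_terms=min_terms)

    # shell-level target: the aggregate FSC of a shell whose terms follow
    # the curve pointwise is the harmonic mean of the per-term values,
    # which sits below the curve at the shell center when the falloff is
    # steep within the shell
    target_fsc = np.empty(len(centers))
    for b in range(len(centers)):
        vals = fsc_curve(target, s[shell_id == b])
        target_fsc[b] = (len(vals) / np.sum(1.0 / np.maximum(vals, 1e-12))
                         if len(vals) else np.nan)
    noise1 = np.fft.rfftn(rng.standard_normal(map1.shape))
    noise2 = np.fft.rfftn(rng.standard_normal(map2.shape))

    # per-term noise requirement: shell-wise signal/noise moments, but the
    # target curve evaluated at each term's own resolution so that steep
    # FSC falloff within a shell is honored
    n_shell_count = int(shell_id.max()) + 1
    for b in range(n_shell_count):
        sel = shell_id == b
        signal = max(0.0, float(np.real(np.mean(F1[sel] * np.conj(F2[sel])))))
        noise_half = 0.5 * float(np.mean(np.abs(F1[sel] - F2[sel]) ** 2))
        if signal <= 0:
            continue
        fsc_t = fsc_curve(target, s[sel])
        with np.errstate(divide="ignore"):
            add = np.where(fsc_t > 0, signal / np.maximum(fsc_t, 1e-12)
                           - signal - noise_half, 0.0)
        if np.any(add < 0):
            warnings.warn(f"shell {b}: target FSC above current; no noise "
                          "removed")
            add = np.maximum(add, 0.0)
        for F, noise in ((F1, noise1), (F2, noise2)):
            pw = float(np.mean(np.abs(noise[sel]) ** 2))
            if pw > 0:
                F[sel] += noise[sel] * np.sqrt(add / pw)

    if target.s_max is not None:
        cut = s > target.s_max
        F1[cut] = 0.0
        F2[cut] = 0.0

    measured = compute_fsc(F1, F2, shell_id)
    info = {
        "shell_centers": centers,
        "target_fsc": target_fsc,
        "measured_fsc": measured,
        "seed": seed,
        "s_max": target.s_max,
    }
    return np.fft.irfftn(F1, s=map1.shape), np.fft.irfftn(F2, s=map2.shape), info
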