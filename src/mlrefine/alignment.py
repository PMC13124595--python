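"""Confidence-weighted Kabsch superposition and rigid-body LLG refinement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Rototranslation:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-6):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is improper (det < 0)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def compose(self, other: "Rototranslation") -> "Rototranslation":
        """self after other: x -> self(other(x))."""
        return Rototranslation(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Rototranslation":
        return Rototranslation(rotation=self.rotation.T,
                               translation=-self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "Rototranslation":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def weighted_kabsch(x_pred: np.ndarray, x_ref: np.ndarray,
                    weights: np.ndarray):
    """Least-squares superposition minimizing sum_i w_i |x_ref - C x_pred|^2.

    Translation from weighted centroids; rotation from the SVD of the
    weighted covariance, with the usual reflection correction. Returns the
    rototranslation C and the transformed coordinates.
    """
    x_pred = np.asarray(x_pred, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x_pred.shape != x_ref.shape:
        raise ValueError("coordinate arrays must have equal shape")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mu_p = wn @ x_pred
    mu_r = wn @ x_ref
    p = x_pred - mu_p
    r = x_ref - mu_r
    # effective rank check: need 3 non-collinear weighted points
    if np.linalg.matrix_rank(p[w > 0], tol=1e-8) < 2:
        raise ValueError("need at least 3 non-collinear weighted points")
    cov = (p * wn[:, None]).T @ r
    u, _, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    pose = Rototranslation(rotation=rot, translation=mu_r - rot @ mu_p)
    return pose, pose.apply(x_pred)


def kabsch_vjp(x_pred: np.ndarray, x_ref_fit: np.ndarray,
               weights: np.ndarray, pose: Rototranslation,
               g_y: np.ndarray, fit_mask: np.ndarray | None = None
               ) -> np.ndarray:
    """Exact vector-Jacobian product through the weighted Kabsch alignment.

    For y = R(x_pred - mu_p) + mu_r with R the optimal rotation, a
    perturbation dx changes y both directly and through (mu_p, R). The
    rotation's first-order response follows from stationarity of
    tr(R A^T), A = sum_j w_j rho_j q_j^T over the fitted sites: with
    G = R A^T symmetric at the optimum, the infinitesimal rotation vector
    omega solves ((tr G) I - G) omega = -sum_j w_j rho_j x (R dq_j).
    Pulling this back yields a closed-form correction to the naive
    "rotate the gradient back" term; the result is exactly orthogonal to
    rigid motions of the prediction, as it must be since the aligned
    output is invariant under them.

    ``fit_mask`` selects the atoms the pose was fitted on (e.g. Calpha);
    ``x_ref_fit`` and ``weights`` cover only those, while ``x_pred`` and
    ``g_y`` cover every transformed atom.
    """
    x_pred = np.asarray(x_pred, dtype=float)
    x_ref_fit = np.asarray(x_ref_fit, dtype=float)
    g_y = np.asarray(g_y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if fit_mask is None:
        fit_mask = np.ones(len(x_pred), dtype=bool)
    wn = w / w.sum()
    p_fit = x_pred[fit_mask]
    mu_p = wn @ p_fit
    mu_r = wn @ x_ref_fit
    q = p_fit - mu_p
    rho = x_ref_fit - mu_r
    R = pose.rotation
    A = (rho * w[:, None]).T @ q          # sum_j w_j rho_j q_j^T
    G = R @ A.T                           # symmetric (psd) at the optimum
    G = 0.5 * (G + G.T)
    N = np.trace(G) * np.eye(3) - G
    a = g_y @ R                           # R^T g_y per atom
    tau = np.cross((x_pred - mu_p) @ R.T, g_y).sum(axis=0)
    m = np.linalg.solve(N, tau)
    corr = -w[:, None] * (np.cross(np.broadcast_to(m, rho.shape), rho) @ R)
    out = a.copy()
    out[fit_mask] += corr - wn[:, None] * (a.sum(axis=0) + corr.sum(axis=0))
    return out


def _rotation_from_axis_angle(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx


def rigid_body_refine(x_array: np.ndarray, b_iso: np.ndarray, llg_fn,
                      n_steps: int = 50, trans_step: float = 0.1,
                      rot_step_deg: float = 0.5, decay: float = 0.9):
    """Gradient ascent of the LLG over a 6-parameter pose.

    ``llg_fn(xyz, b_iso)`` must return (llg, dllg_dxyz, dllg_db). Starting
    from the identity pose (the Kabsch-aligned coordinates), each step moves
    along the normalized translational and rotational gradients by the
    current step sizes; a step that lowers the LLG is reverted and both
    step sizes decay. The rotation acts about the model centroid. The final
    LLG never falls below the starting value.
    """
    x0 = np.asarray(x_array, dtype=float)
    center = x0.mean(axis=0)
    v = np.zeros(3)       # axis-angle, rad
    t = np.zeros(3)       # translation, A

    def pose_coords(v_, t_):
        rot = _rotation_from_axis_angle(v_)
        return (x0 - center) @ rot.T + center + t_

    value, gx, gb = llg_fn(x0, b_iso)
    if not np.isfinite(value):
        raise ValueError("non-finite LLG at the starting pose")
    best = value
    rot_step = np.deg2rad(rot_step_deg)
    ts, rs = trans_step, rot_step
    for _ in range(n_steps):
        x = pose_coords(v, t)
        # translation gradient: sum of per-atom gradients
        g_t = gx.sum(axis=0)
        # rotation gradient: torque of the LLG force field about the center
        g_v = np.cross(x - center - t, gx).sum(axis=0)
        nt = np.linalg.norm(g_t)
        nv = np.linalg.norm(g_v)
        t_new = t + ts * g_t / nt if nt > 0 else t
        v_new = v + rs * g_v / nv if nv > 0 else v
        x_new = pose_coords(v_new, t_new)
        val_new, gx_new, gb_new = llg_fn(x_new, b_iso)
        if val_new > best:
            t, v, best, gx, gb = t_new, v_new, val_new, gx_new, gb_new
        else:
            ts *= decay
            rs *= decay
    rot = _rotation_from_axis_angle(v)
    pose = Rototranslation(rotation=rot,
                           translation=center + t - rot @ center)
    pose.final_gradients = (gx, gb)
    return pose, pose_coords(v, t), best
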