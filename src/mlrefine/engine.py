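"""Two-phase MSA-profile-bias optimization loop.

Each iteration applies a linear bias m = w * m0 + b to the starting cluster
profile, runs the structure predictor, converts confidence to pseudo-B,
aligns the prediction to the reference pose (weighted Kabsch followed by
rigid-body LLG refinement), evaluates the experimental LLG plus an optional
confidence-weighted L2 restraint, and takes an Adam step on (w, b).

Phase 1 ("adventurous") runs several independent traces at high learning
rates with a 3-A resolution cutoff and the L2 restraint switched on; the
best-LLG trace seeds phase 2 ("fine-tuning"), which runs at low learning
rates on all data with early stopping once the LLG stops improving by more
than 0.1 for 50 consecutive iterations.

Gradients flow through coordinates and pseudo-B analytically; the alignment
pose and the per-bin sigma_A values are treated as constants within an
iteration (each is optimized to near-stationarity, so by the envelope
argument their feedback vanishes to first order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    Rototranslation,
    kabsch_vjp,
    rigid_body_refine,
    weighted_kabsch,
)
from .confidence import kabsch_weight, plddt_to_pseudob, pseudob_derivative
from .predictor import StructurePredictor


@dataclass
class ClusterProfileState:
    """Base profile with its multiplicative and additive bias."""

    m0: np.ndarray
    w: np.ndarray = None
    b: np.ndarray = None

    def __post_init__(self):
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.w is None:
            self.w = np.ones_like(self.m0)
        if self.b is None:
            self.b = np.zeros_like(self.m0)
        if self.w.shape != self.m0.shape or self.b.shape != self.m0.shape:
            raise ValueError("bias shapes must match the profile")

    @property
    def m(self) -> np.ndarray:
        return apply_bias(self)


def apply_bias(state: ClusterProfileState) -> np.ndarray:
    """Elementwise m = w * m0 + b; no renormalization or clipping."""
    if state.w.shape != state.m0.shape or state.b.shape != state.m0.shape:
        raise ValueError("bias shapes must match the profile")
    return state.w * state.m0 + state.b


def l2_restraint(x: np.ndarray, x_ref: np.ndarray, weights: np.ndarray):
    """Confidence-weighted squared-distance restraint over Calpha sites.

    Returns (value, d/dx): sum_i w_i |x_i - x_ref,i|^2.
    """
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x.shape != x_ref.shape:
        raise ValueError("coordinate arrays must have equal shape")
    w = np.asarray(weights, dtype=float)
    diff = x - x_ref
    value = float(np.sum(w * np.sum(diff ** 2, axis=1)))
    grad = 2.0 * w[:, None] * diff
    return value, grad


@dataclass
class RefinementConfig:
    """Defaults mirror the published two-phase schedule."""

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
    phase1_d_min: float = 3.0        # phase 1 keeps reflections with d >= 3 A
    seed: int = 0
    trace_jitter: float = 0.01       # seeded per-trace bias perturbation
    # rigid-body search inside each iteration: fewer, larger steps than the
    # standalone pose refiner so the pose can track the data optimum
    rbr_steps: int = 10
    rbr_trans_step: float = 0.3      # A
    rbr_rot_step_deg: float = 2.0
    refit_sigma_a: bool = True


@dataclass
class RefinementTrace:
    """Per-iteration diagnostics of one optimization trace."""

    llg: list = field(default_factory=list)
    l2: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    poses: list = field(default_factory=list)
    stop_reason: str = "max_iter"
    seed: int = 0
    best_llg: float = -np.inf
    best_iteration: int = -1
    best_state: ClusterProfileState | None = None
    best_coords: np.ndarray | None = None

    def as_rows(self):
        return [
            {"iteration": i, "llg": l, "l2": r, "loss": t}
            for i, (l, r, t) in enumerate(zip(self.llg, self.l2, self.loss))
        ]


class Adam:
    """Minimal Adam over a list of arrays with per-array learning rates."""

    def __init__(self, params, lrs, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lrs = lrs
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v, lr in zip(self.params, grads, self.m, self.v,
                                  self.lrs):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g ** 2 - v)
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class RefinementEngine:
    """Binds a predictor, an experimental target and the reference frame."""

    def __init__(self, predictor: StructurePredictor, target,
                 x_ref: np.ndarray, ca_mask: np.ndarray,
                 resid: np.ndarray, config: RefinementConfig,
                 plddt_target: bool = False, align: bool = True):
        self.predictor = predictor
        self.target = target
        self.x_ref = np.asarray(x_ref, dtype=float)
        self.ca_mask = np.asarray(ca_mask, dtype=bool)
        self.resid = np.asarray(resid)
        self.config = config
        self.plddt_target = plddt_target
        self.align = align
        # reference weights from the first, unconditioned prediction: frozen
        _, plddt0 = predictor.predict(
            apply_bias(ClusterProfileState(m0=predictor.m0)))
        self.ref_weights = kabsch_weight(plddt_to_pseudob(plddt0))

    # -- one full iteration ------------------------------------------------

    def iteration(self, state: ClusterProfileState, optimizer: Adam,
                  omega_l2: float, rbr_steps: int | None = None):
        cfg = self.config
        rbr_steps = cfg.rbr_steps if rbr_steps is None else rbr_steps
        m = apply_bias(state)
        coords, plddt = self.predictor.predict(m)
        if self.plddt_target:
            # control mode: maximize mean predicted confidence instead of
            # the experimental likelihood
            value = float(np.mean(plddt))
            g_plddt = np.full(len(plddt), 1.0 / len(plddt))
            g_m = self.predictor.vjp(np.zeros_like(coords), g_plddt)
            optimizer.step([-g_m * state.m0, -g_m])
            return {"llg": value, "l2": 0.0, "loss": -value,
                    "pose": None, "coords": coords}

        pseudo_b_res = plddt_to_pseudob(plddt)
        pseudo_b = pseudo_b_res[self.resid]
        ca = self.ca_mask
        if self.align:
            pose_k, _ = weighted_kabsch(coords[ca], self.x_ref[ca],
                                        self.ref_weights)
        else:
            pose_k = Rototranslation.identity()
        x_aligned = pose_k.apply(coords)
        # refit sigma_A once per iteration; freeze it through the inner
        # rigid-body line searches (a speed knob the schedule permits)
        refit = getattr(self.target, "refit_sigma_a", False)
        self.target.llg(x_aligned, pseudo_b)
        if refit:
            self.target.refit_sigma_a = False
        try:
            pose_r, x_rbr, llg_val = rigid_body_refine(
                x_aligned, pseudo_b, self.target.loss_and_gradients,
                n_steps=rbr_steps, trans_step=cfg.rbr_trans_step,
                rot_step_deg=cfg.rbr_rot_step_deg)
            g_x, g_b = pose_r.final_gradients
        finally:
            self.target.refit_sigma_a = refit
        if not np.isfinite(llg_val):
            raise FloatingPointError("non-finite loss; trace aborted")
        l2_val, g_l2_ca = l2_restraint(x_rbr[ca], self.x_ref[ca],
                                       self.ref_weights)
        loss = -llg_val + omega_l2 * l2_val

        # backprop: d(loss)/dx at the refined pose. The rigid-body pose is
        # an LLG maximizer, so it is treated as constant (envelope
        # argument); the Kabsch pose is differentiated exactly.
        g_loss_x = -g_x
        g_loss_x[ca] += omega_l2 * g_l2_ca
        g_aligned = g_loss_x @ pose_r.rotation
        if self.align:
            g_pred = kabsch_vjp(coords, self.x_ref[ca], self.ref_weights,
                                pose_k, g_aligned, fit_mask=ca)
        else:
            g_pred = g_aligned
        # confidence path: loss depends on pseudo-B through the target
        g_pseudo_b = -g_b
        g_plddt = np.zeros(len(plddt))
        np.add.at(g_plddt, self.resid, g_pseudo_b)
        g_plddt *= pseudob_derivative(plddt)
        g_m = self.predictor.vjp(g_pred, g_plddt)
        optimizer.step([g_m * state.m0, g_m])
        return {"llg": llg_val, "l2": l2_val, "loss": loss,
                "pose": pose_r.compose(pose_k), "coords": x_rbr}

    # -- traces and phases -------------------------------------------------

    def run_trace(self, state: ClusterProfileState, n_iter: int,
                  lr_mul: float, lr_add: float, omega_l2: float,
                  seed: int, early_stop: bool = False) -> RefinementTrace:
        cfg = self.config
        optimizer = Adam([state.w, state.b], [lr_mul, lr_add])
        trace = RefinementTrace(seed=seed)
        stall = 0
        for it in range(n_iter):
            try:
                row = self.iteration(state, optimizer, omega_l2)
            except FloatingPointError:
                trace.stop_reason = f"aborted_iteration_{it}"
                warnings.warn(trace.stop_reason)
                break
            trace.llg.append(row["llg"])
            trace.l2.append(row["l2"])
            trace.loss.append(row["loss"])
            trace.poses.append(row["pose"])
            if row["llg"] > trace.best_llg + cfg.early_stop_threshold:
                stall = 0
            else:
                stall += 1
            if row["llg"] > trace.best_llg:
                trace.best_llg = row["llg"]
                trace.best_iteration = it
                trace.best_state = ClusterProfileState(
                    m0=state.m0, w=state.w.copy(), b=state.b.copy())
                trace.best_coords = row["coords"].copy()
            if early_stop and stall >= cfg.early_stop_window:
                trace.stop_reason = "early_stop"
                break
        return trace


def run_refinement(config: RefinementConfig, predictor: StructurePredictor,
                   target, x_ref: np.ndarray, ca_mask: np.ndarray,
                   resid: np.ndarray, plddt_target: bool = False):
    """Full two-phase schedule; returns (best_coords, final_state, traces).

    Phase 1: ``n_traces`` seeded traces (seed = base + index; each trace's
    initial bias receives a small seeded jitter so traces explore different
    paths) at the phase-1 learning rates, with the L2 restraint and the
    phase-1 resolution cutoff. The best-LLG trace seeds phase 2, run on all
    data with the L2 restraint off, fresh Adam state and early stopping.
    """
    engine = RefinementEngine(predictor, target, x_ref, ca_mask, resid,
                              config, plddt_target=plddt_target)
    cfg = config
    if hasattr(target, "set_resolution_window") and cfg.phase1_d_min:
        target.set_resolution_window(d_min=cfg.phase1_d_min)
    traces = []
    for k in range(cfg.n_traces):
        seed = cfg.seed + k
        rng = np.random.default_rng(seed)
        state = ClusterProfileState(m0=predictor.m0)
        if cfg.trace_jitter:
            state.b += cfg.trace_jitter * rng.standard_normal(state.b.shape)
        traces.append(engine.run_trace(
            state, cfg.n_iter_phase1, cfg.lr_mul, cfg.lr_add, cfg.omega_l2,
            seed=seed))
    if all(not t.llg for t in traces):
        raise RuntimeError("all phase-1 traces aborted")
    best = max(traces, key=lambda t: t.best_llg)
    state = ClusterProfileState(m0=predictor.m0, w=best.best_state.w.copy(),
                                b=best.best_state.b.copy())

    if hasattr(target, "set_resolution_window"):
        target.set_resolution_window()
    trace2 = engine.run_trace(state, cfg.n_iter_phase2, cfg.lr_mul_phase2,
                              cfg.lr_add_phase2, 0.0,
                              seed=cfg.seed + cfg.n_traces, early_stop=True)
    traces.append(trace2)
    candidates = [t for t in traces if t.best_coords is not None]
    winner = max(candidates, key=lambda t: t.best_llg)
    return winner.best_coords, winner.best_state, traces
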