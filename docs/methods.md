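# Methods

`mlrefine` implements maximum-likelihood experimental targets for
predictor-in-the-loop macromolecular refinement: a structure predictor is
treated as a differentiable black box mapping an MSA cluster profile to
coordinates and per-residue confidence, and a linear bias on that profile is
optimized so that the predicted structure maximizes the likelihood of
experimental data — crystallographic intensities or cryo-EM half-maps. This
note records the models, the numerical choices, and what the synthetic test
bed does and does not establish.

## Crystallographic likelihood (LLGI)

Observed intensities `I_o ± σ_I` are reduced to *effective normalized
amplitudes* `E_e` with an attenuation factor `D_obs ∈ [0,1]` per reflection.
The log-likelihood-gain on intensities compares the conditional probability
of `E_e` given the model's normalized amplitude `E_C` against the Wilson
null:

- acentric: Rice density with parameter `d = D_obs·σ_A`,
  variance `1 − d²`;
- centric: Woolfson (cosh) density with the same parameter.

`σ_A`, the resolution-dependent model-quality correlation, is refined per
resolution bin by Newton–Raphson with the analytic first derivative and a
centrally differenced curvature (step 1e-4), safeguarded by monotone
boundary checks and a bisection fallback at non-concave points; results are
clamped to [0.015, 0.99]. Tolerance 1e-4 on σ_A, at most 20 steps,
initialization 0.5 (or the previous iteration's estimate inside the
refinement loop). Only working-set reflections enter LLG and σ_A; a seeded
5% free set is reserved for R-factor reporting.

Numerical stability: `ln I0` via the exponentially scaled Bessel function,
`ln cosh` via `|w| + log1p(e^{−2|w|}) − ln 2`, so the target is finite for
`d → 1`.

Near `σ_A = 0` the likelihood depends on `σ_A` only through `σ_A²`, so the
finite-sample maximum under uninformative data sits at `O(n^{-1/4})` above
zero rather than at the clamp; tests assert this honest behavior.

### Effective amplitudes

The exact construction of `E_e`/`D_obs` from intensity data is part of the
wider likelihood literature; here a moment-matching approximation is used.
Per reflection, intensities are normalized by the bin mean (`z = I/(ε·⟨I/ε⟩)`)
and a truncated-Wilson posterior over the true normalized amplitude `E`
is integrated numerically (801-point grid on [0, 6]) with the Gaussian
intensity-error likelihood. Then

- `E_e` = posterior mean amplitude,
- `D_obs = sqrt(1 − Var_post(E)/Var_prior(E))`, clipped to [0,1],

which is exact in both limits (noiseless: `E_e → E_true`, `D_obs → 1`;
uninformative: posterior = prior, `D_obs → 0`) and, because a posterior
mean's covariance with the truth equals its own variance, makes the mean
`D_obs` track the ensemble correlation `corr(E_e, E_true)`. Precomputed
`E_e`/`D_obs` columns in input files are honored verbatim.

### Structure factors and symmetry

`F(h) = Σ occ·f(s)·exp(−B s²/4)·exp(2πi h·x)` with 4-Gaussian form factors
(C, N, O, S; other elements fall back to a Z-scaled carbon shape; hydrogens
are skipped). Derivatives with respect to coordinates and isotropic B are
closed-form; all losses are pulled back by vector-Jacobian products,
including an exact backward pass through binned Wilson normalization (the
bin scale depends on every amplitude in the bin, giving a rank-one
correction to the diagonal term).

Computation is natively P1. Other space groups are handled by expanding the
model through the group operators inside the structure-factor engine: each
operator contributes a Cartesian affine image of the atoms, and gradients
are folded back through each operator's linear map. Per-reflection
metadata (centric flags, ε multiplicities) comes from the group operations
and is verified against brute-force operator application.

A consequence worth stating: normalized amplitudes are invariant under any
rigid translation of the entire model in P1, so the crystallographic target
cannot pin absolute position there — that gauge freedom is physical, not a
defect. Screw-axis groups (the tests use P2₁2₁2₁) break it, which is where
full 6-parameter pose recovery is exercised.

## Cryo-EM likelihood

Half-map Fourier terms are compared shell by shell: signal
`S = max(0, Re⟨F₁·conj F₂⟩)`, per-averaged-term noise `N = ⟨|F₁−F₂|²⟩/4`,
`D_obs = sqrt(S/(S+N))`, and the averaged map's terms normalized by
`sqrt(S+N)` give `E_e` and `φ_obs`. The per-term LLG is the standard
complex-Gaussian expression in `E_e`, `E_calc`, `Δφ = φ_calc − φ_obs` and
`t = D_obs·σ_A`; per-shell `σ_A` is fitted by bounded scalar maximization
(Brent, tolerance 1e-5) and verified against a 0.001-step grid in tests.
Shells are spherical and uniform in `s`, with undersized shells merged into
neighbors; no directional noise model is attempted. Model Fourier terms use
the same direct-summation engine (on the negated indices to match the FFT
sign convention); both amplitude and phase cotangents are pulled back to
coordinates and B.

Real-space correlation (RSCC) compares model-derived density (inverse FFT
of band-limited model terms, default 2 Å low-pass) to the experimental
grid, globally or over per-residue masks (2.5 Å around the residue's
atoms). The residue-level B update from RSCC uses a bounded linear map
`B = B_min + (B_max−B_min)(1 − clip(RSCC,0,1))` with defaults 20/300 Å² —
monotone, pinned at both ends, deliberately simple.

## FSC model and map degradation

The two-parameter curve `FSC(s) = r/(r + exp(ΔB·s²/4))` is fitted by
bounded least squares (log-r parametrization); its 0.143 crossing has the
closed form `s_max = sqrt(4·ln(r(1/0.143 − 1))/ΔB)`. The empirical
coefficient laws give `r` and `ΔB` as functions of `s_max` over
`s_max ∈ (0.05, 0.7) Å⁻¹`; their self-consistency (curve equals 0.143 at
its own `s_max`) is the package's analytic acceptance quantity.

Degradation to a target resolution adds independent complex Gaussian noise
to both half-maps. The required noise power is computed per term — shell
mean signal, but the target curve evaluated at the term's own `s` — because
a shell's aggregate FSC is the *harmonic* mean of per-term values and the
curve is steep near the cutoff; shell-level reporting uses that harmonic
mean. Terms beyond `s_max` are zeroed exactly; the half-map (not
map-vs-truth) FSC is what is matched. Noise is generated as seeded
real-space white noise, FFT'd, and scaled per term, so Hermitian symmetry
is automatic and the whole operation is bit-reproducible given the seed.

## Confidence, alignment, rigid-body refinement

pLDDT converts to a pseudo-B through the r.m.s.d. relation
`B = (8π²/3)(1.5·e^{4(0.7−pLDDT/100)})²`, and pseudo-B to an empirical
alignment weight: 1 below 11.5 Å², a linear ramp to 0.5 at 40 Å², then
`0.5·exp(−sqrt(B−40))`. The weight collapses rapidly above ~50 Å²
(pLDDT ≲ 74), so only confidently predicted residues steer alignment.
Weights are computed once from the first, unconditioned prediction and
frozen.

Weighted Kabsch superposition (Cα only) solves for the rotation by SVD of
the weighted covariance with reflection correction. Its backward pass is
exact: the optimal rotation's first-order response to a coordinate
perturbation solves `((tr G)I − G)ω = −Σ wⱼ ρⱼ × (R δqⱼ)` with `G = R Aᵀ`
the symmetric stationarity matrix, giving a closed-form VJP whose output is
exactly orthogonal to rigid motions of the prediction. Differentiating
through the alignment (rather than treating the pose as a constant) proved
essential: with a detached pose the profile optimization reliably diverges,
because spurious rigid-motion gradient components are never cancelled.

Rigid-body refinement ascends the LLG over a 6-parameter axis-angle +
translation pose about the weighted centroid: normalized gradient steps
with fixed nominal sizes, a step that lowers the LLG is reverted and both
sizes decay ×0.9. Standalone defaults are 50 steps of 0.1 Å / 0.5°; inside
the refinement loop the engine uses 10 steps of 0.3 Å / 2° so the pose can
track the data optimum from the alignment pose in a few evaluations. The
rigid-body pose is treated as a constant in the engine's backward pass — it
maximizes the LLG itself, so its feedback vanishes to first order — while
the per-bin σ_A refit enjoys the same envelope argument (and is frozen
during the inner pose search purely for speed).

## The two-phase optimization loop

Per iteration: bias the profile (`m = w⊙m₀ + b`, no clipping or
renormalization — the literal linear form; the toy decoder tolerates values
outside [0,1] and this is documented as a risk for probability-consuming
predictors), predict, convert confidence, align (weighted Kabsch +
rigid-body), evaluate `L = −LLG + ω_L2·Σ wᵢ‖xᵢ−x_ref,i‖²` (Cα, computed on
the pose-refined coordinates), and take one Adam step on (w, b) with
separate learning rates.

Defaults follow the published schedule: phase 1 runs 3 traces × 100
iterations at `lr_mul = 1.0`, `lr_add = 0.05`, `ω_L2 = 1e-11`, with a 3-Å
resolution cutoff (implemented as keeping reflections with d ≥ 3 Å); the
best-LLG trace seeds phase 2 (500 iterations, both rates 1e-3, restraint
off, fresh Adam state) with early stopping once the LLG fails to improve
the running best by more than 0.1 for 50 consecutive iterations. Per-trace
seeds are `base_seed + trace_index`; each trace's initial additive bias
receives a small (σ = 0.01) seeded jitter so traces explore distinct paths
— the stand-in for the stochasticity a dropout-bearing neural predictor
provides. The engine keeps the best-LLG state and coordinates seen, not the
last ones. A mean-pLDDT target mode exists as a control experiment hook.

Gradient flow: loss → coordinates (and pseudo-B) → through the rigid-body
rotation and the exact Kabsch VJP → predictor VJP → (w, b) via
`∂L/∂w = ∂L/∂m ⊙ m₀`. The confidence path (target B-factors → pLDDT →
profile) is included analytically.

## Toy predictor and synthetic data

The toy predictor decodes the cluster-mean profile linearly into per-residue
φ/ψ torsion offsets (two fixed orthonormal 23-channel readout directions,
gain 0.05 rad per unit profile deviation) applied to an ideal-geometry
N/CA/C/O backbone built by NeRF; coordinate Jacobians with respect to
torsions are the classic axis cross-product form, so the full predictor VJP
is closed-form. By construction an additive bias exists that reproduces any
target torsion set exactly. pLDDT is a smooth function of pooled-column
softmax entropy calibrated to the 75–90 range typical of converged
predictions — necessary realism, since the empirical alignment weights are
effectively zero below pLDDT ≈ 74.

Study conditions (generator defaults): a 10-residue chain in two
conformations differing by ±35° φ/ψ changes on a 3-residue loop (>2 Å Cα
r.m.s.d. over the perturbed region), orthorhombic P1 cell with 7 Å padding;
reflections to 3 Å with 5% fractional intensity error plus a 1% floor, 8
equal-count bins, 5% free set; 32³ half-map grids with shell noise at 25%
of signal power; 12-cluster × 23-channel profiles from Dirichlet columns.
Resolution-degradation experiments use a separate wide-box pair (64³ grid,
~127 Å cell) so that 6–10 Å cutoffs are spanned by several 500-term shells.
These sizes keep the complete two-phase schedule (3×100 + early-stopped
500) at roughly 15–20 s per seed on one CPU, so the 20-seed recovery
experiments in both modalities run inside a normal test session.

What the toy bed shows — and does not. It exercises every equation,
gradient and scheduling rule end to end and demonstrates that biasing the
profile against either experimental likelihood moves the predicted
conformation toward the data-generating one. It does not emulate a learned
structure manifold, co-evolutionary attractors, dropout-driven trace
diversity, solvent, multi-chain packing, or real noise statistics; transfer
of the *magnitudes* of improvement to real predictors and deposited data is
outside what these tests can establish.

## Known limitations

- Flat-solvent correction is available conceptually but default OFF; no
  bulk-solvent mask model, anisotropic B, twinning or anomalous signal.
- Cryo-EM noise is spherical; no directional model, no sphere extraction
  around the model, single-chain maps only.
- Domain-wise alignment (predicted-aligned-error splitting) is not
  implemented; alignment is single-body with a config hook left open.
- MI analysis treats clusters as equally weighted soft samples with
  per-cluster column renormalization; muting is residue-level (both members
  of a ranked pair). Heat-map normalization is min–max.
- The intensity-error model is Gaussian; no profile-fitting or French–Wilson
  tabulation beyond the quadrature posterior.
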