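# Methods

## The generative model

Neuronal dynamics follow a one-state bilinear ODE over four regions in
fixed order (F, ACC, S, SMA):

    ẋ = (A + u_mod · B) x + C · u_drive

* `A` — baseline effective connectivity, units 1/s. Off-diagonal entries
  are free parameters where the model's structure mask allows them; the
  diagonal is fixed at −0.5 1/s and never estimated, which guarantees a
  stable resting point for any admissible off-diagonal configuration.
* `B` — modulation of connectivity by the up-regulation condition
  (one matrix per modulatory input; the protocol has exactly one).
  Modulation is only allowed on connections present in `A` and never on
  self-connections.
* `C` — gain of the visual-feedback driving input. The feedback display
  is present for the whole training run (it is merely static during
  baseline blocks), so the drive box-car is sustained from run onset;
  the up-regulation box-car enters only through the bilinear term. In
  transfer runs (self-regulation without feedback) the feedback drive is
  silenced and replaced by a volitional drive scaled by the subject's
  engagement (see the cohort section).

Each region's activity drives a balloon–Windkessel cascade — vasodilatory
signal s, normalised inflow f, venous volume v, deoxyhemoglobin q:

    ṡ = x − κ s − γ (f − 1)
    ḟ = s
    τ v̇ = f − v^{1/α}
    τ q̇ = f·E(f)/E₀ − v^{1/α}·q/v,   E(f) = 1 − (1 − E₀)^{1/f}

observed through the classical (non-revised) BOLD equation in percent
signal change:

    y = 100·V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v)),
    k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2.

Hemodynamic constants default to the standard values κ = 0.64 1/s,
γ = 0.32 1/s, τ = 2 s, α = 0.32, E₀ = 0.4, V₀ = 0.04, shared across
regions; per-region multiplicative deviations of κ and τ (log-scale) can
be estimated with tight priors. The observation coefficients are defined
in exactly one place (`bold_coefficients`).

Integration is fixed-step classical RK4 at 16 micro-time bins per TR
(TR = 1.5 s by default, so dt ≈ 94 ms); both choices are configurable.
The kernel is numba-compiled and batched over parameter sets, which makes
a finite-difference Jacobian cost roughly one batched forward
integration. Refinement to 32 bins changes no BOLD sample by more than
1e-4 (tested), and the integrator tracks positivity of f, v, q, reporting
the first offending region and volume on failure. Separately acquired
runs are always integrated from rest independently — concatenation is an
operation on data and design matrices, never on integrator state.

## The synthetic cohort

The generator emulates the neurofeedback training protocol that motivates
the package: 2 sessions × 4 training runs (8 total) per subject, each run
alternating 4 baseline and 3 up-regulation blocks (30 s per block by
default — the protocol text gives no duration, so this is a convention
recorded in the cohort manifest), a transfer run without feedback, and
18 subjects split into 9 learners and 9 non-learners.

Ground-truth parameters are Gaussian draws per free entry, redrawn until
both A and A+B are stable and all driving gains are responsive
(truncation at two SDs below the mean gain; a subject whose display
evokes no response has no usable data). Defaults:

| parameter | mean | SD | rationale |
|---|---|---|---|
| A off-diagonals | 0.15 | 0.05 | moderate positive coupling, stable |
| B[F→SMA], learners | 0.4 | 0.1 | the group effect under study |
| B[F→SMA], non-learners | 0.0 | 0.1 | no systematic target modulation |
| B, other edges | 0.0 | 0.05 | idiosyncratic nuisance modulation, half the focal SD |
| C[input region] | 0.06 | 0.02 | ≈1–2% peak BOLD, realistic block-design amplitude |

Observation noise is i.i.d. Gaussian per region. The default SD is set
per subject so that the ratio of the clean response's temporal SD
(per-region means removed) to the noise SD equals the configured SNR
(default 1) — the standard definition in DCM simulation work. Optional
low-order cosine drift can be added.

For the learning ranking each subject receives two extra runs. The
*baseline-reference* run is the pre-training response: feedback drive on,
learned modulation off. The *transfer* run has the feedback drive
silenced and a sustained volitional drive scaled by engagement — 1 for
learners, 0 for non-learners by default. This encodes the phenotype the
ranking is meant to detect: learners carry their regulation skill into
the no-feedback test and show increased SMA activity, non-learners lose
the feedback-driven activity and show a decrease. Without some
post-training drive the bilinear model would output exactly zero for
every transfer run and no distribution-based learning measure could
work.

What the generator does **not** emulate: the closed feedback loop itself
(thermometer computation), reward magnitudes, habituation or motivation
drift, physiological (cardiac/respiratory) noise, scanner drift beyond
the optional cosines, and spatial/voxel structure. A green recovery test
therefore establishes that the estimator works under the model's own
assumptions at realistic amplitude and noise — not robustness to the
model violations real data would add.

## Model spaces

Step 1 crosses 7 baseline-coupling variants with 2 driving-input sites
(F = "top-down" family, S = "bottom-up" family), 14 models. The variants
span axis directionality (descending F→ACC→S, ascending, bilateral) ×
(forward-only vs bilateral node↔SMA links), plus exactly one direct S–F
bypass variant that removes the ACC relay. The step-1 winner — bilateral
axis, bilateral node↔SMA links, input at F — is exposed directly as
`winning_architecture()`.

Step 2 fixes that architecture and varies which connections the
up-regulation condition modulates: 13 models in three origin families —
Frontal (3: each subset of {F→ACC, F→SMA}), ACC (5: three single edges,
the two axis edges, all three), Striatal (5: over the pathway
{S→ACC, S→SMA, ACC→SMA} — each direct edge, both, the relayed
S→ACC→SMA route, the full pathway; the striatum reaches the target
directly or through the ACC relay only). The published source is
internally inconsistent about the striatal count; the package follows
the 13-model total and the published model numbering (3/5/5) and exposes
every mask in the space manifest so users can substitute their own
enumeration. A fully-modulated variant (all ten connections) supports
the parameter-level group comparison.

## Inversion (variational Laplace)

Observation model: y = g(θ) + X_c β + ε with ε ~ N(0, e^{−λ} I). `g` is
the batched DCM forward model; `X_c` holds one run-indicator column per
concatenated run (plus optional per-run cosines), entering linearly with
one coefficient per (region, column). A single shared log-precision λ is
a deliberate simplification of richer noise models (documented
limitation).

The Gaussian posterior q(θ) = N(m, S) is optimised by Gauss–Newton
ascent on

    F = E_q[log p(y|θ, λ)] − KL(q(θ) ‖ p(θ)) − KL(q(λ) ‖ p(λ))

with Levenberg–Marquardt damping: a proposed step that would lower F is
rejected and retried with stronger damping, so the accepted free-energy
trace is non-decreasing by construction. λ is re-optimised by 1-D Newton
within every step evaluation. Initialisation is at the prior mean with
no random restarts — inversion is deterministic. Convergence: |ΔF| <
0.01 nats on three consecutive accepted steps, at most 128 iterations;
exhaustion of admissible uphill steps also terminates (the optimum at
working precision). On a linear forward model with fixed λ the scheme is
conjugate and F reproduces the analytic log evidence (tested to 1e-3
nats; observed agreement is near machine precision).

Priors: zero-mean shrinkage Gaussians with variance 1/64 on A
off-diagonals, 1/16 on B, 1/4 on C (the conventional scale for 1/s
couplings), N(0, 0.05²) on hemodynamic log-deviations, N(2, 16) on λ,
and N(0, 1) on confound coefficients — run offsets in percent-signal
units are order 1, and a much more diffuse offset prior lets the
confounds absorb the sustained-drive plateau that identifies C.
Jacobians use one-sided finite differences with steps of 1e-3 × prior SD
(clipped to [1e-5, 1e-2]), evaluated in a single batched integration;
central differences are available (`fd_central`) but double the cost
without measurable benefit on the recovery benchmarks.

## Random-effects model selection

The Dirichlet RFX scheme iterates subject responsibilities
u_nk ∝ exp(l_nk + ψ(α_k) − ψ(Σα)) with α = α₀ + Σ_n u_n (α₀ = 1 by
default). Exceedance probabilities use the exact Beta tail for two
alternatives and Dirichlet Monte Carlo otherwise (10⁶ draws by default,
seed recorded). The Bayesian omnibus risk compares the RFX free energy
against the evidence of the fixed equal-frequency null,
BOR = 1/(1 + exp(F₁ − F₀)); protection is pxp = xp(1−BOR) + BOR/K.

Family inference applies the size correction at the evidence level: the
within-family model prior is uniform conditional on the family, so each
subject's family evidence is log mean_k exp(l_nk) over members, and the
RFX scheme runs over families with a symmetric prior. Under exchangeable
evidence the expected family frequencies are uniform regardless of
family sizes. (Running the model-level fixed point with per-model prior
mass 1/|family| instead exhibits a rich-get-richer bias of the
variational fixed point and was rejected.)

BMA weights each model's posterior means by the softmax of free energies
over the chosen scope (uniform model prior); parameters absent from a
model contribute zero with full weight. The group comparison defaults to
the fully-modulated model's parameters (scope = that single model),
matching the convention of comparing groups within one representative
modulatory structure; any scope over the 13-model space is available.

## Group comparison and learning ranking

Learner vs non-learner differences per modulatory connection use the
pooled-variance two-sample t-test (Welch available by flag), two-sided,
with Bonferroni correction over the number of modulatory connections
tested. Zero pooled variance with equal means returns p = 1 by
convention.

Learning is ranked by the 1-Wasserstein distance between the SMA BOLD
sample distributions of the baseline-reference and transfer runs:
Gaussian-kernel densities (Scott's bandwidth) on a grid spanning both
sample sets ± 3 bandwidths, W1 = ∫|CDF_a − CDF_b|, signed by the
direction of the mean change. Degenerate (zero-spread) samples become
point masses handled analytically. A raw-sample W1 estimator
(`wasserstein_samples`) provides an independent route that agrees within
grid tolerance. The default label rule is the sign of the signed
distance with ties labelled non-learner; a median split is available.
Whether the compared samples are per-volume values of the whole run
(default) or restricted to condition blocks is a `scope` option — the
underlying description of the measure is ambiguous on this point.

## Numerical and degenerate-input conventions

* Probability vectors are normalised to 1 ± 1e-9; posterior covariances
  are symmetric with eigenvalues ≥ −1e-10.
* Exceedance ties (a probability-zero event) go to the first index.
* Non-finite data, mismatched TRs or region orders, overlapping event
  blocks, and missing TR sidecars are hard errors, never silent
  defaults.
* Failed inversions inside a log-evidence grid are recorded as missing
  with a log entry; a subject failing on every model aborts.

## Known limitations

* The noise model is a single i.i.d. Gaussian component shared across
  regions; AR structure and region-specific precisions are not
  implemented.
* The estimator is the classical per-subject scheme; hierarchical
  (empirical-Bayes) group models and fixed-effects BMS are out of scope.
* The step-1/step-2 mask enumerations are a documented canonical choice
  constrained by the textual description of the spaces; the exact
  published matrices are only available graphically.
* Parameter recovery at SNR 1 is validated on data generated by the
  model itself; the A-matrix entries are weakly identified at this noise
  level and their estimates lean on the shrinkage priors.
* Transfer-run volitional drive is a modelling device of the synthetic
  world (see above), not an estimate of any real mechanism.
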