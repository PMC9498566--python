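# Methods

## Model and estimation

The package estimates relative risks for right-censored survival data
under the Cox proportional hazards assumption: the hazard of sample *i*
is λ(t | z_i) = λ₀(t) exp(θ_i), with the baseline hazard λ₀ left
unspecified. Two estimators of the log hazard ratio θ are provided.

**CNT (Cox network with TGDR).** θ_i = W2ᵀ tanh(W1 z_i + b), a single
hidden layer of h nodes (default 10) with tanh activation. The training
objective is the log partial likelihood of the scores,
l = Σ_{δ=1}[θ_i − log Σ_{t_j ≥ t_i} e^{θ_j}], maximized by threshold
gradient descent: per iteration, exact backpropagated gradients ΔW2,
ΔW1, Δb are computed on the full sample (the partial likelihood couples
samples through risk sets, so there is no minibatching), and the masked
updates are

- W2 ← W2 + α_k · L2 ⊗ ΔW2 with L2_j = I(|ΔW2_j| ≥ τ · max_j |ΔW2_j|),
- W1 ← W1 + α_k · L1 ⊗ ΔW1 with L1_jl = I(|ΔW1_jl| ≥ τ · max_l |ΔW1_j·|)
  — each hidden node's row is thresholded against its own maximum,
- b ← b + α_k · Δb, unmasked,

with α_k = α₀ · η^k, defaults α₀ = 0.01 and η = 0.99. W1 and W2 are
initialized exactly at zero; b ~ N(0, 0.01·I) from the seeded generator
so that all hidden nodes are active from the start.

**CT (linear Cox with TGDR).** θ_i = βᵀ z_i with β initialized at zero
and a single-level threshold I(|Δβ_j| ≥ τ · max_j |Δβ_j|). For the
linear model the update uses the *per-sample mean* gradient (the summed
gradient divided by N), which keeps the default learning rate
well-scaled across sample sizes; for the network the summed-likelihood
gradient is used as written above, which is what makes the default
α₀ = 0.01 productive at the benchmark sample sizes.

Both estimators share the sparsity mechanism: an entry whose indicator
never fires is never touched and ends the fit bit-exactly zero. A
variable counts as selected iff its entry of W12 = W2ᵀW1 (CNT) or of β
(CT) is exactly nonzero; no epsilon is involved.

## Numerical choices

- **Risk sets and ties.** Non-strict risk sets {j : t_j ≥ t_i}
  throughout, with tied event times sharing the full risk set (Breslow).
  The likelihood and its score-level gradient are computed after a
  single stable sort via suffix accumulation (O(N log N)) with a
  max-shift in the log-sum-exp; both are verified against naive O(N²)
  risk-set enumeration in the tests.
- **C-index.** Harrell's definition: pairs (i, j) with t_i < t_j are
  comparable iff sample i had the event; tied scores earn half credit.
- **Precision of the network fit.** The CNT training loop runs in
  single precision, the customary working precision for neural
  networks; the partial-likelihood value and gradient are computed in
  double precision each iteration and cast. All public quantities
  (gradients from `backward`, likelihood values, the CT fit) are double
  precision. A consequence worth knowing: the all-zero (W1, W2) point
  is an *exact* stationary point of the likelihood — the score gradient
  sums to zero and the hidden activations are constant across samples —
  so the earliest updates are of rounding-noise magnitude and are
  amplified exponentially along the leading signal direction. The fit
  leaves the stationary point within a few tens of iterations; useful K
  values start around 50.
- **Degenerate cases.** A dataset with no events raises; non-finite
  losses raise naming the iteration; an all-zero gradient stops the fit
  early with a warning rather than dividing by a zero maximum. An empty
  selection yields precision 0 and F1 0.

## Tuning

τ and K are selected by V-fold cross-validation (default V = 5),
stratified by event status so every training part contains events. The
default criterion is the Verweij–van Houwelingen cross-validated
partial likelihood — the full-data likelihood at fold-trained
parameters minus the training-fold likelihood, summed over folds —
chosen over fold-wise C-index for stability with small event counts
(the C-index criterion is available as an option). Because TGDR
training is a single trajectory, all K values on the grid are scored
from one fit per (τ, fold) using parameter checkpoints. Ties are broken
toward larger τ, then smaller K (the sparser model). Default grids:
τ ∈ {0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0}, K ∈ {50, 100, 200, 300, 500}.
For very high-dimensional data τ can simply be fixed near 1.

## Synthetic data

The generator emulates omics-like benchmark conditions with a known
sparse truth. Covariates are MVN(0, Σ) with Σ_lk = e^{−|l−k|} — sampled
exactly through the stationary AR(1) recursion z_k = ρ z_{k−1} +
√(1−ρ²) ε_k, ρ = e^{−1} — or Σ = I. The log relative risk is, by
setting and scenario:

- Setting 1: unit linear effects on variables 1..up; Setting 2: strong
  effects β₁ = 1 on the first up/2 and weak effects β₂ = 0.3 on the
  next up/2; Setting 3: unit linear effects with total dimension fixed.
- Scenario 2 adds z²_{up+1} + z²_{up+2}; scenario 3 adds
  5(z_up z_{up−1} + z_{up−1} z_{up−2}); scenario 4 adds both. Setting 3
  has a single form with both. The numbers of quadratic and interaction
  terms are fixed at two.

Event times follow the Cox model with Weibull baseline hazard
λ₀(t) = s r^s t^{s−1}, defaults r = 0.1, s = 2, by inverse transform:
T = (1/r)(−log U · e^{−lp})^{1/s}. Censoring times are independent
exponentials whose rate is calibrated to a target censoring fraction
(default 30%) by root-finding on E[1 − e^{−rate·T}] over a fixed
200,000-draw Monte-Carlo sample of T with a dedicated seed, so one rate
is shared by every replicate of a design. A variable is "important" —
the ground truth for selection metrics — iff its index appears anywhere
in the hazard; this is the only definition under which TP + FN is a
fixed known count. The linear-effect count `up` defaults to 10.

What the generator does *not* emulate: measurement noise and batch
effects, heavy-tailed or skewed expression distributions, block or
pathway-structured correlation, informative censoring, and covariate
main effects entangled with time (non-proportional hazards). Passing
benchmarks on these replicates therefore demonstrates correctness of
the estimation machinery under the stated generating model, not
robustness on real omics data.

## Desk-scale evaluation protocol

The benchmark experiments (`run_experiment`, `scripts/acceptance.py`,
`tests/test_acceptance.py`) use 10 replicates per design at p = 1000,
N = 1000 with an independent same-size test replicate per training
replicate, and a reduced tuning grid — τ ∈ {0.8, 0.9, 0.95, 1.0}
(the region both estimators occupy under sparse truth; sparser grids
below 0.8 are never competitive there and dominate compute),
K ∈ {50, 100, 200, 300, 500}, 5 folds. Reported quantities are means
over replicates; per-replicate seeds derive deterministically from one
master seed.

## Known limitations

- Single hidden layer only; other activations, dropout, multi-layer
  variants are out of scope.
- Efron's tie correction, time-dependent covariates and left truncation
  are not implemented; ties are handled by Breslow's convention.
- The zero-initialization stationary point means very small K (below
  ~25) yields models that have not left the initialization; the K grid
  should start at 50.
- The selection ROC traces a τ-grid at the selected K; tracing K or
  both jointly is not implemented.
- CT's mean-gradient scaling makes its trajectory length (in likelihood
  units) bounded by α₀/(1−η) per unit gradient; with the default decay
  the fit relies on CV choosing K large enough, and the estimate is a
  shrunken (ridge-like for small τ) version of the Cox MLE — scores are
  proportional, so ranking metrics are unaffected.
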