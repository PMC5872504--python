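# Methods

## Model

### Hidden state process

The regulatory state of `n` genes at time `k` is a binary gene activity
profile `X_k`. A Boolean network with perturbation (BNp) updates it as
`X_{k+1} = f(X_k) ⊕ n_{k+1}`, with `f` the per-gene Boolean rules and
`n_{k+1}` i.i.d. Bernoulli(p_{k+1}) flips. The flip probability `p_k` is
unknown; it carries a Beta(a, b) prior, redrawn independently at every
time step. Because the hyperparameters are shared across steps, the chain
obtained after integrating `p` out is homogeneous with the beta-binomial
transition kernel

    M_{ij} = Γ(d+a) Γ(n−d+b) Γ(a+b) / [Γ(a) Γ(b) Γ(a+b+n)],

where `d` is the Hamming distance between state `j` and `f(state i)`. One
marginal matrix `M` per class is therefore built and reused for all
transitions. All flip kernels are strictly positive, so the chain is
irreducible and has a unique steady state `π = πM`; trajectories are
assumed to start in it, so `π` is also the distribution of `X_1`.

### Observation process

Expressions are conditionally Gaussian given the hidden bit, with a
normal-gamma prior keyed to the bit:

    λ_j(k) ~ Gamma(α₀, rate β₀)
    θ_j(k) | λ ~ N(μ₀ + δ₀ x_j(k), (κ₀λ)^{-1})
    y_j(k) | θ, λ ~ N(θ, λ^{-1}).

The gamma prior is parameterized by *rate*: the conjugate update
`β₁ = β₀ + κ₀(y − μ₀ − δ₀x)² / (2(κ₀+1))` is only consistent with that
convention, so it is adopted throughout. Marginalizing θ and λ gives the
per-observation kernel K2, a Student-t with 2α₀ degrees of freedom,
location μ₀ + δ₀x and squared scale β₀(κ₀+1)/(α₀κ₀). The per-time
observation vector Φ(k) stacks the product of the n K2 factors for each of
the 2^n candidate states.

### Classifier

The effective class-conditional density of a trajectory 𝒴 of length `m`
is computed by the forward (sum-product) recursion

    Π(1) = π ∘ Φ(1),   Π(k+1) = [Mᵀ Π(k)] ∘ Φ(k+1),   p(𝒴|S=s) = ‖Π(m)‖₁.

The IBR rule predicts class 0 iff `E[c]·p(𝒴|0) ≥ (1−E[c])·p(𝒴|1)`, with
`E[c] = a_c/(a_c+b_c)` the mean of the beta prior on the class-0
probability. The decision uses the prior mean only — there is no posterior
update of any parameter; that is what distinguishes the intrinsically
Bayesian robust rule from the optimal Bayesian classifier, which is out of
scope here.

## Numerical choices

- **Log space everywhere.** The literal product forms underflow badly:
  Γ(a+b+n) overflows for moderate arguments and Φ's product of n Student-t
  densities with β₀ ~ 1e4–1e5 underflows at n = 10. All gamma ratios go
  through `gammaln`, Φ is carried as log values, and the forward messages
  are L1-normalized at every step with the log normalizers accumulated.
  This is the standard HMM scaling and is exact in real arithmetic; a test
  confirms the scaled recursion equals the unscaled one where the latter
  is feasible.
- **Steady state by linear solve.** `π` is obtained by replacing one
  balance equation of `(Mᵀ − I)π = 0` with the normalization constraint
  and solving the dense system — exact to solver precision, and cheap at
  2^10 states. The residual `‖πM − π‖∞` is checked (< 1e−10) before the
  vector is accepted. Power iteration exists only in the test oracles.
- **Tie-breaking.** Exact zero log posterior odds predict class 0, with no
  epsilon; identical class models therefore always predict 0.
- **State encoding.** Gene 1 is the most significant bit of the state
  index (`index = Σ x_j 2^{n−j}`); any consistent convention works (a
  relabeling-symmetry test verifies this), this one is fixed and
  round-trips exactly.
- **Networks as sparse logic.** Rules are stored as per-gene regulator
  lists plus truth tables over the regulators' joint states (first listed
  regulator = most significant bit) and expanded once to a full
  2^n-entry transition map. The cell-cycle CycD input, set by
  extracellular signals, is fixed to the constant 0 and stored as an
  ordinary zero-regulator rule, as is the silenced p27 rule in the mutant.

## Simulator

The generator samples the exact hierarchy the classifier assumes: label
`S ~ Bernoulli(1 − E[c])`, initial state from the class's marginal-TPM
steady state, then per step a fresh `p ~ Beta(a, b)`, Bernoulli flips, and
finally λ, θ, y per gene and time. Drawing labels from the prior *mean*
rather than first drawing `c ~ Beta(a_c, b_c)` per trajectory is
distributionally identical at the level of expected error, which is the
quantity being estimated, and keeps datasets simpler to reason about.
Each trajectory uses its own `SeedSequence`-spawned stream, so a dataset
is bit-reproducible from `(seed, hyperparameters, networks)` regardless of
batching. A `p_fixed` hook exists solely so tests can force the noiseless
orbit.

What the simulator does *not* emulate: real single-cell data are not
Gaussian around two fixed levels, genes share technical covariates, and
sampling intervals drift. Passing tests show internal consistency of
model, classifier and simulator — not that the model fits any particular
real dataset.

## Hyperparameters

| name | meaning | default |
|------|---------|---------|
| a, b | beta prior on flip probability p; E[p] = a/(a+b) ≈ 0.01 | 1, 100 |
| a_c, b_c | beta prior on class-0 probability; E[c] = 0.5 | 10, 10 |
| α₀, β₀ | gamma shape/rate of expression precision; E[λ] = α₀/β₀ | 100, 1e4 |
| κ₀ | precision multiplier of the mean prior | 100 |
| μ₀ | baseline (gene off) expression level | 10 |
| δ₀ | expression shift when a gene is on | 40 |

Defaults are the baseline study conditions; the expected observation noise
s.d. under them is √(β₀(κ₀+1)/((α₀−1)κ₀)) ≈ 10, one quarter of δ₀.

## Error estimation and sweeps

Classification error is estimated by Monte Carlo: simulate `n_reps`
labeled trajectories, classify, count disagreements, attach the binomial
95% half-width `1.96·√(e(1−e)/n_reps)`. The default `n_reps = 2000` keeps
the half-width ≤ ~0.022 while a full seven-parameter trend battery runs in
well under a minute (the forward pass is batched across trajectories into
2^n × N matrix products). Sweeps vary one of {m, a, b, α₀, β₀, κ₀, δ₀}
against a fixed base configuration, rebuilding `M` and `π` only when
(a, b) change, and reuse the same seed at every grid point so grid points
share common random numbers; differences between points then reflect the
parameter rather than resampling noise. Sweep runs emit a structured log
line (config hash, seed, elapsed time) per grid point.

Expected qualitative behavior, each verified as an ordered pair of error
estimates in the acceptance suite: error decreases in m, α₀, b, κ₀ and
δ₀, and increases in a and β₀. Exact curve values depend on unstated
replication settings, so trends — not digitized figure values — are the
reproduction target.

## Known limitations

- Cost is O(m·4^n) per likelihood evaluation (dense 2^n × 2^n matrix);
  fine at n = 10, impractical far beyond n ≈ 14.
- The observation model assumes one cell per trajectory; averaged
  multi-cell measurements, non-Gaussian noise and EM-style parameter
  estimation are out of scope.
- The class prior enters only through E[c], per the IBR decision form;
  posterior updating of c or of any other parameter is not implemented.
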