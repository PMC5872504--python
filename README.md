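# ibrnet

Intrinsically Bayesian robust (IBR) classification of single-cell
gene-expression *trajectories* generated by Boolean gene regulatory
networks.

## The problem

Phenotype classification from bulk expression data loses the timing of
regulatory events. If instead a single cell is profiled at `m` consecutive
time points, the observed trajectory reflects the dynamics of the
underlying gene regulatory network, and classification can exploit those
dynamics — for example discriminating a wild-type network from a mutated,
cancer-associated one.

`ibrnet` models the hidden regulatory dynamics of `n` genes as a **Boolean
network with perturbation** (BNp):

    X_{k+1} = f(X_k) ⊕ n_{k+1},

where `X_k ∈ {0,1}^n` is the gene activity profile, `f` the Boolean wiring,
and `n_{k+1}` an i.i.d. Bernoulli(p_{k+1}) flip vector that makes the
induced 2^n-state Markov chain irreducible. Observed expressions are
Gaussian around state-dependent means:

    y_j(k) | θ, λ ~ N(θ_j(k), λ_j(k)^{-1}),
    λ_j(k) ~ Gamma(α₀, β₀),   θ_j(k) | λ ~ N(μ₀ + δ₀·x_j(k), (κ₀λ)^{-1}),

with a Beta(a, b) prior on the perturbation probability and a
Beta(a_c, b_c) prior on the class-0 prior probability c. All uncertain
parameters are integrated out against their priors, giving the *effective
class-conditional density* p(𝒴 | S=s) of a trajectory 𝒴 = [Y₁ … Y_m]. It is
computed exactly by a forward (sum-product) recursion over the 2^n states
with the beta-marginal transition matrix

    M_{ij} = Γ(d+a) Γ(n−d+b) Γ(a+b) / [Γ(a) Γ(b) Γ(a+b+n)],

`d` the Hamming distance between state j and f(state i), the chain started
in its steady state π = πM. The IBR classifier then decides

    ψ(𝒴) = 0  iff  E[c] · p(𝒴|S=0) ≥ (1 − E[c]) · p(𝒴|S=1).

The package ships the 10-gene mammalian cell-cycle Boolean network (genes
CycD, Rb, p27, E2F, CycE, CycA, Cdc20, Cdh1, UbcH10, CycB) in two variants:
wild-type (class 0) and a cancerous mutant in which p27 is permanently shut
down (class 1), plus the full generative simulator and a Monte Carlo
harness for error-versus-hyperparameter sweeps.

## Worked example

```python
import numpy as np
import ibrnet as ib

hs, ho = ib.load_config()                      # baseline hyperparameters
cm0, cm1 = ib.build_cell_cycle_pair(hs, ho)    # wild-type vs p27-mutant

# simulate one trajectory (m = 10) from the mutant class and classify it
rng = np.random.default_rng(0)
X, _ = ib.sample_state_trajectory(cm1.net, hs, m=10, rng=rng, pi=cm1.pi)
Y = ib.sample_observation_trajectory(X, ho, rng)
r = ib.classify(Y, cm0, cm1, hs)
print(f"predicted class: {r.predicted}")
print(f"log p(Y|S=0) = {r.log_density_0:.3f}")
print(f"log p(Y|S=1) = {r.log_density_1:.3f}")
print(f"log posterior odds = {r.log_posterior_odds:.3f}")
```

prints

```
predicted class: 1
log p(Y|S=0) = -415.832
log p(Y|S=1) = -384.754
log posterior odds = -31.078
```

the mutant trajectory is correctly assigned to class 1: its log density
under the mutant model is about 31 nats higher than under the wild-type
model, which dominates the balanced class prior (E[c] = 0.5).

Monte Carlo error estimation under a noisier observation prior
(α₀ = 10, β₀ = 1e5, so the expected expression noise is large):

```python
hs = ib.StateHyperparameters(a=1, b=100)
ho = ib.ObservationHyperparameters(alpha0=10, beta0=1e5, kappa0=100, mu0=10, delta0=40)
cm0, cm1 = ib.build_cell_cycle_pair(hs, ho)
for m in (2, 5, 10):
    est = ib.estimate_error(cm0, cm1, hs, m=m, n_reps=2000, seed=1)
    print(f"m={m:2d}  error = {est.error:.4f} +/- {est.ci95_halfwidth:.4f}")
```

```
m= 2  error = 0.4010 +/- 0.0215
m= 5  error = 0.3300 +/- 0.0206
m=10  error = 0.2885 +/- 0.0199
```

longer trajectories carry more of the networks' dynamics and the error
falls accordingly (± values are 95% binomial confidence half-widths).

## Command line

```sh
ibrnet simulate  --net0 wt.json --net1 mut.json --config base.yaml \
                 --m 10 --n-traj 100 --seed 7 --out-dir sim/
ibrnet classify  --net0 wt.json --net1 mut.json --config base.yaml \
                 --trajectories sim/trajectory_0000.tsv --out calls.csv
ibrnet experiment sweep --param delta0 --grid 10,20,40 --m 5 \
                 --n-reps 2000 --seed 7 --out sweep.csv
ibrnet experiment plot  --csv sweep.csv --out sweep.png
```

Networks are JSON (per-gene regulator lists plus truth tables; see
`src/ibrnet/data/`), trajectories are TSV with a gene-name header, and the
hyperparameter config is a YAML/JSON mapping with keys
`a, b, a_c, b_c, alpha0, beta0, kappa0, mu0, delta0`.

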