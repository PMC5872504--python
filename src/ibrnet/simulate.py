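"""Generative sampler for the full Bayesian hierarchy.

One labeled trajectory is produced by walking the model top-down: draw the
class label from the (mean of the) beta class prior, start the hidden chain
in the steady state of that class's beta-marginal transition matrix, then at
every step redraw the perturbation probability from its Beta(a, b) prior,
flip each gene independently with that probability on top of the Boolean
update, and finally emit expressions through the normal-gamma / Gaussian
observation model.

Reproducibility: a dataset is generated from one integer seed via
``numpy.random.SeedSequence``; each trajectory gets its own spawned child
stream, so regeneration is bit-identical and independent of batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import ObservationHyperparameters, StateHyperparameters, beta_mean
from .classifier import ClassModel
from .network import BooleanNetwork, state_index

__all__ = [
    "ObservationParameters",
    "LabeledDataset",
    "sample_state_trajectory",
    "sample_observation_trajectory",
    "sample_labeled_dataset",
]


@dataclass
class ObservationParameters:
    """Latent draws behind one simulated trajectory (kept for diagnostics)."""

    theta: np.ndarray | None = None  # (m, n) Gaussian means
    lam: np.ndarray | None = None  # (m, n) Gaussian precisions
    perturb_probs: np.ndarray | None = None  # (m-1,) p_k draws
    perturb_vectors: np.ndarray | None = None  # (m-1, n) flip indicator draws


@dataclass
class LabeledDataset:
    trajectories: np.ndarray  # (N, m, n) expressions
    labels: np.ndarray  # (N,) class bits
    seed: int
    provenance: dict = field(default_factory=dict)


def sample_state_trajectory(
    net: BooleanNetwork,
    h_state: StateHyperparameters,
    m: int,
    rng: np.random.Generator,
    pi: np.ndarray | None = None,
    p_fixed: float | None = None,
) -> tuple[np.ndarray, ObservationParameters]:
    """Sample a hidden Boolean state trajectory of length m.

    The initial state is drawn from ``pi`` (the steady state of the
    marginal transition matrix; computed here when not supplied).  Each
    subsequent step draws p ~ Beta(a, b) — or uses ``p_fixed``, a hook for
    noiseless-orbit checks — then flips each gene independently with
    probability p after applying the Boolean update.
    """
    if m < 1:
        raise ValueError(f"trajectory length must be >= 1, got {m}")
    if pi is None:
        from .network import marginal_tpm, steady_state

        pi = steady_state(marginal_tpm(net, h_state.a, h_state.b))
    n = net.n
    states = np.empty((m, n), dtype=np.uint8)
    fmap = net.transition_map()
    idx = int(rng.choice(2**n, p=pi))
    shifts = np.arange(n - 1, -1, -1)
    states[0] = (idx >> shifts) & 1
    probs = np.empty(m - 1)
    flips = np.empty((m - 1, n), dtype=np.uint8)
    for k in range(m - 1):
        p = float(rng.beta(h_state.a, h_state.b)) if p_fixed is None else float(p_fixed)
        nk = (rng.random(n) < p).astype(np.uint8)
        nxt = ((fmap[idx] >> shifts) & 1).astype(np.uint8)
        states[k + 1] = nxt ^ nk
        idx = state_index(states[k + 1])
        probs[k] = p
        flips[k] = nk
    return states, ObservationParameters(perturb_probs=probs, perturb_vectors=flips)


def sample_observation_trajectory(
    X: np.ndarray,
    h: ObservationHyperparameters,
    rng: np.random.Generator,
    return_params: bool = False,
):
    """Sample expressions for a given hidden state trajectory.

    For every gene j and time k:  lam ~ Gamma(alpha0, rate beta0),
    theta ~ N(mu0 + delta0*x, (kappa0 lam)^-1),  y ~ N(theta, lam^-1).
    """
    X = np.asarray(X)
    if X.ndim != 2 or not np.isin(X, (0, 1)).all():
        raise ValueError("state trajectory must be a binary (m, n) matrix")
    lam = rng.gamma(shape=h.alpha0, scale=1.0 / h.beta0, size=X.shape)
    theta = rng.normal(h.mu0 + h.delta0 * X, np.sqrt(1.0 / (h.kappa0 * lam)))
    Y = rng.normal(theta, np.sqrt(1.0 / lam))
    if return_params:
        return Y, ObservationParameters(theta=theta, lam=lam)
    return Y


def sample_labeled_dataset(
    cm0: ClassModel,
    cm1: ClassModel,
    h_state: StateHyperparameters,
    m: int,
    N: int,
    seed: int,
) -> LabeledDataset:
    """Generate N labeled trajectories of length m from the two-class model.

    Labels are Bernoulli with P(S=1) = 1 - E[c]; given the label, the
    class's hierarchy is sampled.  Trajectory i uses the i-th child stream
    of ``SeedSequence(seed)``, so the dataset is reproducible bit-for-bit.
    """
    if N < 1:
        raise ValueError(f"dataset size must be >= 1, got {N}")
    if m < 1:
        raise ValueError(f"trajectory length must be >= 1, got {m}")
    if cm0.net.n != cm1.net.n:
        raise ValueError("class models disagree on the number of genes")
    n = cm0.net.n
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(N + 1)
    ec = beta_mean(h_state.a_c, h_state.b_c)
    labels = (np.random.default_rng(children[0]).random(N) < (1.0 - ec)).astype(np.int8)
    Ys = np.empty((N, m, n))
    for i in range(N):
        rng = np.random.default_rng(children[i + 1])
        cm = cm1 if labels[i] else cm0
        X, _ = sample_state_trajectory(cm.net, h_state, m, rng, pi=cm.pi)
        Ys[i] = sample_observation_trajectory(X, cm.h_obs, rng)
    provenance = {
        "m": m,
        "N": N,
        "state_hyperparameters": {k: getattr(h_state, k) for k in ("a", "b", "a_c", "b_c")},
        "observation_hyperparameters_class0": {
            k: getattr(cm0.h_obs, k) for k in ("alpha0", "beta0", "kappa0", "mu0", "delta0")
        },
        "observation_hyperparameters_class1": {
            k: getattr(cm1.h_obs, k) for k in ("alpha0", "beta0", "kappa0", "mu0", "delta0")
        },
        "network_labels": [cm0.net.label, cm1.net.label],
    }
    return LabeledDataset(trajectories=Ys, labels=labels, seed=seed, provenance=provenance)
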