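"""Conjugate-prior kernels for the Bayesian observation and state models.

The observation model is Gaussian with a normal-gamma prior keyed to the
hidden Boolean state of each gene: the precision lambda has a Gamma(alpha0,
beta0) prior (rate parameterization), and given lambda the mean theta is
normal with mean mu0 + delta0*x and precision kappa0*lambda.  Integrating
theta and lambda out gives the marginal density K2 of a single expression
value — a Student-t — which this module evaluates in log space.  The
per-time-point observation vector Phi stacks the product of K2 factors over
genes for every hidden network state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import gammaln

from .network import all_states

__all__ = [
    "StateHyperparameters",
    "ObservationHyperparameters",
    "beta_mean",
    "beta_variance",
    "log_k2",
    "log_phi",
    "load_config",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class StateHyperparameters:
    """Beta-prior shapes for the perturbation probability (a, b) and the
    class-0 prior probability (a_c, b_c)."""

    a: float = 1.0
    b: float = 100.0
    a_c: float = 10.0
    b_c: float = 10.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_c", "b_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ObservationHyperparameters:
    """Normal-gamma prior parameters of the expression model.

    alpha0/beta0: shape and rate of the gamma prior on the precision;
    kappa0: precision multiplier of the conditional mean prior;
    mu0: baseline expression level; delta0: expression coefficient, i.e.
    the shift in mean expression when a gene is on.
    """

    alpha0: float = 100.0
    beta0: float = 1e4
    kappa0: float = 100.0
    mu0: float = 10.0
    delta0: float = 40.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "kappa0", "delta0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = {
    "a": 1.0,
    "b": 100.0,
    "a_c": 10.0,
    "b_c": 10.0,
    "alpha0": 100.0,
    "beta0": 1e4,
    "kappa0": 100.0,
    "mu0": 10.0,
    "delta0": 40.0,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None):
    """Read hyperparameters from a YAML/JSON mapping.

    Unspecified keys fall back to the package defaults; unknown keys are
    rejected.  Returns ``(StateHyperparameters, ObservationHyperparameters)``.
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML 1.1 reads exponent literals like 1.0e5 as strings; coerce
        for k, v in loaded.items():
            try:
                cfg[k] = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"config key {k!r} must be numeric, got {v!r}") from None
    if overrides:
        unknown = set(overrides) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    hs = StateHyperparameters(a=cfg["a"], b=cfg["b"], a_c=cfg["a_c"], b_c=cfg["b_c"])
    ho = ObservationHyperparameters(
        alpha0=cfg["alpha0"],
        beta0=cfg["beta0"],
        kappa0=cfg["kappa0"],
        mu0=cfg["mu0"],
        delta0=cfg["delta0"],
    )
    return hs, ho


def beta_mean(a: float, b: float) -> float:
    """Mean a/(a+b) of a Beta(a, b) distribution."""
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    return a / (a + b)


def beta_variance(a: float, b: float) -> float:
    """Variance ab / [(a+b)^2 (a+b+1)] of a Beta(a, b) distribution."""
    if a <= 0 or b <= 0:
        raise ValueError("beta shape parameters must be positive")
    return a * b / ((a + b) ** 2 * (a + b + 1))


def log_k2(y, x, h: ObservationHyperparameters):
    """Log marginal density of one expression value given its hidden bit.

    With theta and lambda integrated against the normal-gamma prior,

        K2 = (2 pi)^{-1/2} (kappa0/kappa1)^{1/2}
             * Gamma(alpha1)/Gamma(alpha0) * beta0^alpha0 / beta1^alpha1,

    with kappa1 = kappa0 + 1, alpha1 = alpha0 + 1/2 and
    beta1 = beta0 + kappa0 (y - mu0 - delta0 x)^2 / (2 (kappa0 + 1)).
    Vectorized over ``y`` and ``x`` (broadcast together).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    kappa1 = h.kappa0 + 1.0
    alpha1 = h.alpha0 + 0.5
    resid = y - h.mu0 - h.delta0 * x
    beta1 = h.beta0 + h.kappa0 * resid**2 / (2.0 * kappa1)
    out = (
        -0.5 * np.log(2.0 * np.pi)
        + 0.5 * (np.log(h.kappa0) - np.log(kappa1))
        + gammaln(alpha1)
        - gammaln(h.alpha0)
        + h.alpha0 * np.log(h.beta0)
        - alpha1 * np.log(beta1)
    )
    return out if out.ndim else float(out)


def log_k2_bits(y_k: np.ndarray, h: ObservationHyperparameters) -> np.ndarray:
    """log K2 of each gene's observation under both bit hypotheses.

    Returns an array of shape ``y_k.shape + (2,)``: ``[..., 0]`` for the
    gene off, ``[..., 1]`` for the gene on.
    """
    y_k = np.asarray(y_k, dtype=float)
    return np.stack([log_k2(y_k, 0, h), log_k2(y_k, 1, h)], axis=-1)


def log_phi(y_k, h: ObservationHyperparameters, n: int) -> np.ndarray:
    """Log observation vector over all 2^n hidden states for one time point.

    Entry i is sum_j log K2(y_j | x^i_j), the log joint marginal density of
    the n observed expressions given hidden state x^i.  Computed as a rank-1
    update of the all-off total so the cost is O(2^n * n) multiplies.
    """
    y_k = np.asarray(y_k, dtype=float)
    if y_k.shape != (n,):
        raise ValueError(f"observation vector has shape {y_k.shape}, expected ({n},)")
    l0 = log_k2(y_k, 0, h)
    l1 = log_k2(y_k, 1, h)
    bits = all_states(n).astype(float)
    return float(np.sum(l0)) + bits @ (l1 - l0)
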