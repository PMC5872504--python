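"""Monte Carlo error estimation and hyperparameter sweeps.

The classification error of the IBR rule has no printed closed form here;
it is estimated by simulating labeled trajectories from the generative
hierarchy and counting disagreements.  Sweeps hold a base configuration
fixed, vary one hyperparameter (or the trajectory length m) over a grid,
and reuse the same seed at every grid point so that grid points share
common random numbers — differences between points then reflect the
parameter, not resampling noise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import (
    DEFAULT_CONFIG,
    ObservationHyperparameters,
    StateHyperparameters,
    beta_mean,
)
from .classifier import ClassModel, _forward_batch, log_prior_odds
from .data import load_cell_cycle
from .simulate import sample_labeled_dataset

logger = logging.getLogger(__name__)

SWEEPABLE = ("m", "a", "b", "alpha0", "beta0", "kappa0", "delta0")
_STATE_KEYS = ("a", "b", "a_c", "b_c")
_OBS_KEYS = ("alpha0", "beta0", "kappa0", "mu0", "delta0")


@dataclass(frozen=True)
class ErrorEstimate:
    """Misclassification fraction with a binomial 95% confidence interval."""

    error: float
    n_reps: int
    ci95_halfwidth: float
    m: int
    seed: int
    params: dict = field(default_factory=dict)


def build_cell_cycle_pair(
    h_state: StateHyperparameters | None = None,
    h_obs: ObservationHyperparameters | None = None,
) -> tuple[ClassModel, ClassModel]:
    """Class models for the wild-type (S=0) and p27-mutant (S=1) networks."""
    h_state = h_state or StateHyperparameters()
    h_obs = h_obs or ObservationHyperparameters()
    cm0 = ClassModel.build(load_cell_cycle("wild-type"), h_state, h_obs)
    cm1 = ClassModel.build(load_cell_cycle("p27-mutant"), h_state, h_obs)
    return cm0, cm1


def estimate_error(
    cm0: ClassModel,
    cm1: ClassModel,
    h_state: StateHyperparameters,
    m: int,
    n_reps: int,
    seed: int,
) -> ErrorEstimate:
    """Monte Carlo estimate of the IBR classification error.

    Simulates ``n_reps`` labeled trajectories, classifies them (densities
    computed in one batched forward pass per class), and returns the
    disagreement fraction.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    ds = sample_labeled_dataset(cm0, cm1, h_state, m=m, N=n_reps, seed=seed)
    ld0 = _forward_batch(ds.trajectories, cm0)
    ld1 = _forward_batch(ds.trajectories, cm1)
    odds = log_prior_odds(h_state) + ld0 - ld1
    pred = np.where(odds >= 0, 0, 1)
    err = float(np.mean(pred != ds.labels))
    hw = 1.96 * np.sqrt(err * (1.0 - err) / n_reps)
    return ErrorEstimate(
        error=err,
        n_reps=n_reps,
        ci95_halfwidth=float(hw),
        m=m,
        seed=seed,
        params={**{k: getattr(h_state, k) for k in _STATE_KEYS},
                **{k: getattr(cm0.h_obs, k) for k in _OBS_KEYS}},
    )


def _models_for(cfg: dict) -> tuple[ClassModel, ClassModel, StateHyperparameters]:
    hs = StateHyperparameters(**{k: cfg[k] for k in _STATE_KEYS})
    ho = ObservationHyperparameters(**{k: cfg[k] for k in _OBS_KEYS})
    cm0, cm1 = build_cell_cycle_pair(hs, ho)
    return cm0, cm1, hs


def sweep(
    parameter: str,
    grid,
    base_config: dict | None = None,
    m_list=(5,),
    n_reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Error-versus-hyperparameter table on the cell-cycle class pair.

    ``parameter`` is one of m, a, b, alpha0, beta0, kappa0, delta0; the
    base configuration holds every other hyperparameter at its default (or
    the supplied override).  Returns one row per (grid value, m).
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; choose from {SWEEPABLE}")
    cfg0 = dict(DEFAULT_CONFIG)
    if base_config:
        unknown = set(base_config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg0.update(base_config)
    cfg_hash = hashlib.sha256(json.dumps(cfg0, sort_keys=True).encode()).hexdigest()[:12]
    rows = []
    cache: dict[tuple, tuple] = {}
    t0 = time.perf_counter()
    for value in grid:
        cfg = dict(cfg0)
        ms = list(m_list)
        if parameter == "m":
            ms = [int(value)]
        else:
            cfg[parameter] = float(value)
        key = (cfg["a"], cfg["b"], cfg["a_c"], cfg["b_c"],
               cfg["alpha0"], cfg["beta0"], cfg["kappa0"], cfg["mu0"], cfg["delta0"])
        if key not in cache:
            cache[key] = _models_for(cfg)
        cm0, cm1, hs = cache[key]
        for m in ms:
            est = estimate_error(cm0, cm1, hs, m=int(m), n_reps=n_reps, seed=seed)
            rows.append(
                {
                    "parameter": parameter,
                    "value": value,
                    "m": int(m),
                    "error": est.error,
                    "ci95_halfwidth": est.ci95_halfwidth,
                    "n_reps": n_reps,
                    "seed": seed,
                }
            )
            logger.info(
                "sweep %s=%s m=%d error=%.4f (config %s, seed %d, %.1fs elapsed)",
                parameter, value, m, est.error, cfg_hash, seed, time.perf_counter() - t0,
            )
    return pd.DataFrame(rows)
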