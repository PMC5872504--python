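"""Boolean networks with perturbation (BNp) and their induced Markov chains.

A BNp updates the binary state of ``n`` genes as

    X_{k+1} = f(X_k) XOR n_{k+1},

where ``f`` is the deterministic wiring of the network and the perturbation
vector ``n_{k+1}`` has i.i.d. Bernoulli(p_{k+1}) components.  The XOR noise
makes the induced 2^n-state Markov chain irreducible, so the chain has a
unique, strictly positive steady-state distribution.  This module represents
the network, builds the chain's transition probability matrices — either
conditional on the perturbation probability ``p`` or with ``p`` integrated
against a Beta(a, b) prior — and solves for steady states.

State encoding
--------------
A state vector (gene activity profile) ``x = [x_1, ..., x_n]`` maps to the
integer index ``sum_j x_j * 2^(n-j)``: gene 1 is the most significant bit.
The mapping round-trips exactly via :func:`state_index` / :func:`state_bits`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln


def state_index(bits: Sequence[int]) -> int:
    """Encode a binary gene-activity profile as a state index.

    Gene 1 (the first entry) is the most significant bit.
    """
    idx = 0
    for b in bits:
        b = int(b)
        if b not in (0, 1):
            raise ValueError(f"state entries must be 0 or 1, got {b}")
        idx = (idx << 1) | b
    return idx


def state_bits(index: int, n: int) -> np.ndarray:
    """Decode a state index back to its length-``n`` binary vector."""
    if not 0 <= index < 2**n:
        raise ValueError(f"index {index} out of range for n={n}")
    return np.array([(index >> (n - 1 - j)) & 1 for j in range(n)], dtype=np.uint8)


def all_states(n: int) -> np.ndarray:
    """All 2^n state vectors as a (2^n, n) binary matrix, row i = state i."""
    idx = np.arange(2**n, dtype=np.uint32)
    shifts = np.arange(n - 1, -1, -1, dtype=np.uint32)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.uint8)


def hamming_distance(x: Sequence[int], y: Sequence[int]) -> int:
    """Number of positions at which two equal-length binary vectors differ."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return int(np.count_nonzero(x != y))


@dataclass(frozen=True)
class GeneFunction:
    """Boolean update rule of one gene.

    ``table`` holds the output bit for every joint assignment of the
    regulators, indexed with the *first* listed regulator as the most
    significant bit (same convention as the global state encoding).
    """

    target: str
    regulators: tuple[int, ...]  # zero-based indices into the gene list
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.table) != 2 ** len(self.regulators):
            raise ValueError(
                f"{self.target}: table has {len(self.table)} entries, "
                f"expected {2 ** len(self.regulators)}"
            )
        if any(v not in (0, 1) for v in self.table):
            raise ValueError(f"{self.target}: truth-table entries must be 0 or 1")


@dataclass(eq=False)
class BooleanNetwork:
    """A Boolean network: one update rule per gene plus a free-form label."""

    genes: list[str]
    functions: list[GeneFunction]
    label: str = ""
    _fmap: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if n < 1:
            raise ValueError("network needs at least one gene")
        if len(self.functions) != n:
            raise ValueError("need exactly one update function per gene")
        for f in self.functions:
            for r in f.regulators:
                if not 0 <= r < n:
                    raise ValueError(f"{f.target}: regulator index {r} out of range")

    @property
    def n(self) -> int:
        return len(self.genes)

    def evaluate(self, x: Sequence[int]) -> np.ndarray:
        """Apply the noiseless update f to one state vector."""
        x = np.asarray(x)
        if x.shape != (self.n,):
            raise ValueError(f"state has shape {x.shape}, expected ({self.n},)")
        out = np.empty(self.n, dtype=np.uint8)
        for i, f in enumerate(self.functions):
            idx = 0
            for r in f.regulators:
                idx = (idx << 1) | int(x[r])
            out[i] = f.table[idx]
        return out

    def transition_map(self) -> np.ndarray:
        """Index of f(x) for every state index x, as a length-2^n array.

        Computed once and cached; this is the deterministic part of the
        chain from which all transition matrices derive.
        """
        if self._fmap is None:
            states = all_states(self.n)
            nxt = np.zeros(2**self.n, dtype=np.int64)
            weights = 1 << np.arange(self.n - 1, -1, -1)
            for i, f in enumerate(self.functions):
                if f.regulators:
                    sub = states[:, list(f.regulators)]
                    w = 1 << np.arange(len(f.regulators) - 1, -1, -1)
                    joint = sub @ w
                    bit = np.asarray(f.table)[joint]
                else:
                    bit = np.full(2**self.n, f.table[0])
                nxt += bit.astype(np.int64) * weights[i]
            self._fmap = nxt
        return self._fmap

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "BooleanNetwork":
        genes = list(d["genes"])
        if "n" in d and d["n"] != len(genes):
            raise ValueError("declared n does not match gene list length")
        g2i = {g: i for i, g in enumerate(genes)}
        funcs = []
        for spec in d["functions"]:
            funcs.append(
                GeneFunction(
                    target=spec["target"],
                    regulators=tuple(g2i[r] for r in spec["regulators"]),
                    table=tuple(int(v) for v in spec["table"]),
                )
            )
        order = {f.target: f for f in funcs}
        try:
            funcs = [order[g] for g in genes]
        except KeyError as e:
            raise ValueError(f"no update function for gene {e}") from None
        return cls(genes=genes, functions=funcs, label=d.get("label", ""))

    @classmethod
    def from_json(cls, path: str | Path) -> "BooleanNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "genes": list(self.genes),
            "functions": [
                {
                    "target": f.target,
                    "regulators": [self.genes[r] for r in f.regulators],
                    "table": list(f.table),
                }
                for f in self.functions
            ],
            "label": self.label,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


# -- transition matrices -------------------------------------------------


def _hamming_matrix(net: BooleanNetwork) -> np.ndarray:
    """d[i, j] = Hamming distance between state j and f(state i)."""
    fmap = net.transition_map()
    idx = np.arange(2**net.n, dtype=np.int64)
    return np.bitwise_count(fmap[:, None] ^ idx[None, :]).astype(np.int64)


def conditional_tpm(net: BooleanNetwork, p: float) -> np.ndarray:
    """Transition matrix of the BNp chain for a known perturbation probability.

    Entry (i, j) = p^d (1-p)^(n-d) with d the Hamming distance between
    state j and f(state i); each row is a product-Bernoulli distribution
    and sums to one.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"perturbation probability must lie in (0, 1), got {p}")
    d = _hamming_matrix(net)
    n = net.n
    with np.errstate(divide="ignore"):
        logm = d * np.log(p) + (n - d) * np.log1p(-p)
    return np.exp(logm)


def marginal_tpm(net: BooleanNetwork, a: float, b: float) -> np.ndarray:
    """Transition matrix with the perturbation probability integrated out.

    Under a Beta(a, b) prior on p, the transition kernel is beta-binomial
    in the Hamming distance d:

        M[i, j] = Gamma(d+a) Gamma(n-d+b) Gamma(a+b)
                  / [Gamma(a) Gamma(b) Gamma(a+b+n)].

    All gamma factors are evaluated in log space.
    """
    if a <= 0 or b <= 0:
        raise ValueError(f"beta shape parameters must be positive, got a={a}, b={b}")
    n = net.n
    dvals = np.arange(n + 1, dtype=float)
    logk1 = (
        gammaln(dvals + a)
        + gammaln(n - dvals + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        - gammaln(a + b + n)
    )
    return np.exp(logk1)[_hamming_matrix(net)]


def steady_state(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution pi of a row-stochastic matrix: pi = pi M.

    Solved as a linear system, replacing one balance equation with the
    normalization constraint.  Requires an irreducible chain (guaranteed
    here by strictly positive perturbation kernels); the result is checked
    against the fixed-point equation before it is returned.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("transition matrix must be square")
    rows = M.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-8) or np.any(M < 0):
        raise ValueError("input is not row-stochastic")
    N = M.shape[0]
    A = M.T - np.eye(N)
    A[-1, :] = 1.0
    rhs = np.zeros(N)
    rhs[-1] = 1.0
    pi = np.linalg.solve(A, rhs)
    if np.any(pi < -tol):
        raise ArithmeticError("steady-state solve produced negative probabilities")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if np.max(np.abs(pi @ M - pi)) > tol:
        raise ArithmeticError("steady-state solve did not satisfy pi = pi M")
    return pi
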