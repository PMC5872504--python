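"""Independent numerical oracles used to cross-check the closed forms.

Everything here is deliberately written the slow, literal way — quadrature,
power iteration, explicit path enumeration in linear arithmetic — so it
shares no code path with the log-space sum-product implementation it checks.
"""

import itertools
import math
import warnings

import numpy as np
from scipy import integrate
from scipy import stats


def k1_quadrature(d, n, a, b):
    """Beta-binomial transition kernel entry by direct quadrature over p."""
    val, _ = integrate.quad(
        lambda p: stats.beta.pdf(p, a, b) * p**d * (1.0 - p) ** (n - d),
        0.0,
        1.0,
        epsabs=1e-14,
        epsrel=1e-12,
    )
    return val


def k2_double_quadrature(y, x, h, lam_hi=None, theta_half=None):
    """Marginal observation density by nested quadrature over theta, lambda."""
    mu = h.mu0 + h.delta0 * x
    if lam_hi is None:
        lam_hi = (h.alpha0 + 40.0 * math.sqrt(h.alpha0)) / h.beta0
    if theta_half is None:
        theta_half = 40.0 / math.sqrt(h.kappa0 * h.alpha0 / h.beta0)

    def inner(lam):
        f = lambda th: (
            stats.norm.pdf(y, th, 1.0 / math.sqrt(lam))
            * stats.norm.pdf(th, mu, 1.0 / math.sqrt(h.kappa0 * lam))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(f, mu - theta_half, mu + theta_half, epsabs=1e-14, limit=300)
        return val * stats.gamma.pdf(lam, h.alpha0, scale=1.0 / h.beta0)

    val, _ = integrate.quad(inner, 0.0, lam_hi, epsabs=1e-13, limit=200)
    return val


def student_t_logpdf(y, x, h):
    """The K2 marginal written as its Student-t closed form."""
    scale = math.sqrt(h.beta0 * (h.kappa0 + 1.0) / (h.alpha0 * h.kappa0))
    return stats.t.logpdf(y, df=2.0 * h.alpha0, loc=h.mu0 + h.delta0 * x, scale=scale)


def phi_literal(y_k, h, n):
    """The 2^n observation vector evaluated as the literal product form."""
    pref = (
        h.beta0**h.alpha0
        / math.sqrt(2.0 * math.pi)
        * math.sqrt(h.kappa0 / (h.kappa0 + 1.0))
        * math.gamma(h.alpha0 + 0.5)
        / math.gamma(h.alpha0)
    )
    out = np.empty(2**n)
    for i in range(2**n):
        prod = pref**n
        for j in range(n):
            xij = (i >> (n - 1 - j)) & 1
            beta1 = h.beta0 + h.kappa0 * (y_k[j] - h.mu0 - h.delta0 * xij) ** 2 / (
                2.0 * (h.kappa0 + 1.0)
            )
            prod *= beta1 ** -(h.alpha0 + 0.5)
        out[i] = prod
    return out


def marginal_tpm_quadrature(net, a, b):
    """Beta-marginal transition matrix built entry-wise from quadrature."""
    n = net.n
    size = 2**n
    k1 = [k1_quadrature(d, n, a, b) for d in range(n + 1)]
    M = np.empty((size, size))
    for i in range(size):
        bits_i = [(i >> (n - 1 - j)) & 1 for j in range(n)]
        fx = net.evaluate(bits_i)
        for jdx in range(size):
            d = sum(((jdx >> (n - 1 - j)) & 1) != fx[j] for j in range(n))
            M[i, jdx] = k1[d]
    return M


def stationary_power_iteration(M, tol=1e-15, max_iter=200000):
    v = np.full(M.shape[0], 1.0 / M.shape[0])
    for _ in range(max_iter):
        v2 = v @ M
        v2 /= v2.sum()
        if np.max(np.abs(v2 - v)) < tol:
            return v2
        v = v2
    raise RuntimeError("power iteration did not converge")


def brute_force_log_density(Y, net, h_state, h_obs):
    """Trajectory marginal likelihood by explicit sum over all state paths."""
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    M = marginal_tpm_quadrature(net, h_state.a, h_state.b)
    pi = stationary_power_iteration(M)
    phis = [phi_literal(Y[k], h_obs, n) for k in range(m)]
    total = 0.0
    for path in itertools.product(range(2**n), repeat=m):
        val = pi[path[0]] * phis[0][path[0]]
        for k in range(m - 1):
            val *= M[path[k], path[k + 1]] * phis[k + 1][path[k + 1]]
        total += val
    return math.log(total)
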