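"""Independent brute-force oracles used only by the test suite.

The posterior oracle integrates the joint Bernoulli-Beta model over the
ordered regions of the (r_m, r_s) unit square by nested Gauss-Legendre
product quadrature on a 2000x2000 node grid, in log space. The Beta
kernels are polynomials, so the inner integrals are numerically exact
and the outer error is spectrally small (self-convergence ~1e-13,
checked in the suite). It shares no code path with the package's
posterior methods.
"""

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import betaln, logsumexp


def _ordered_logmass(p_lo, q_lo, p_hi, q_hi, n=2000):
    """log of the integral of x^p_lo (1-x)^q_lo y^p_hi (1-y)^q_hi over x < y."""
    gx, gw = leggauss(n)
    y = 0.5 * (gx + 1.0)
    wy = 0.5 * gw
    x = y[:, None] * y[None, :]  # inner nodes scaled into [0, y_j]
    with np.errstate(divide="ignore"):
        lin = p_lo * np.log(x) + q_lo * np.log1p(-x) + np.log(wy)[:, None]
    log_inner = logsumexp(lin, axis=0) + np.log(y)
    with np.errstate(divide="ignore"):
        log_outer = p_hi * np.log(y) + q_hi * np.log1p(-y) + np.log(wy) + log_inner
    return logsumexp(log_outer)


def oracle_log_marginals(k_m, n_m, k_s, n_s, alpha=1.0, beta=1.0, n=2000):
    """Log marginal likelihoods (less, equal, greater) by grid integration.

    Uses the Bernoulli-sequence likelihood without binomial
    coefficients, matching the package's convention (coefficients cancel
    across hypotheses).
    """
    pm, qm = alpha - 1 + k_m, beta - 1 + n_m - k_m
    ps, qs = alpha - 1 + k_s, beta - 1 + n_s - k_s
    lb = betaln(alpha, beta)
    # region prior mass is exactly 1/2 (both rates share one Beta prior)
    log_less = _ordered_logmass(pm, qm, ps, qs, n) - 2 * lb + np.log(2.0)
    log_greater = _ordered_logmass(ps, qs, pm, qm, n) - 2 * lb + np.log(2.0)
    log_eq = betaln(alpha + k_m + k_s, beta + n_m + n_s - k_m - k_s) - lb
    return np.array([log_less, log_eq, log_greater])


def oracle_posterior(k_m, n_m, k_s, n_s, alpha=1.0, beta=1.0, n=2000):
    logs = oracle_log_marginals(k_m, n_m, k_s, n_s, alpha, beta, n)
    p = np.exp(logs - logs.max())
    return p / p.sum()


#: Diverse pooled-count fixtures spanning the regimes the analysis sees:
#: 2-5 trials of 2500 bins, rates ~0.01-0.3, null to strong effects.
POSTERIOR_FIXTURES = [
    # (k_m, n_m, k_s, n_s)
    (125, 2500, 50, 2500),
    (50, 2500, 125, 2500),
    (75, 2500, 75, 2500),
    (0, 2500, 0, 2500),
    (1, 2500, 0, 2500),
    (60, 5000, 50, 5000),
    (150, 5000, 100, 5000),
    (300, 7500, 150, 7500),
    (150, 7500, 300, 7500),
    (200, 7500, 210, 7500),
    (375, 12500, 250, 12500),
    (30, 200, 30, 200),
    (5, 100, 15, 100),
    (10, 150, 20, 150),
    (2, 50, 8, 50),
    (80, 400, 40, 400),
    (12, 5000, 45, 5000),
    (700, 7500, 640, 7500),
    (25, 2500, 100, 5000),
    (90, 2500, 180, 5000),
    (400, 5000, 350, 5000),
    (8, 2500, 8, 2500),
]
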