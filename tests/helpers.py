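"""Independent oracles used by the test suite.

These deliberately re-derive quantities from first principles (full
hypergeometric-support enumeration, direct step-up formulas, analytic
identities) so they stay independent of the code paths they check.
"""

import numpy as np
from scipy import stats

_TOL = 1 + 1e-10


def brute_force_fisher(a: int, b: int, c: int, d: int):
    """Two-sided (minimum-likelihood) and one-sided Fisher P by full
    enumeration of the hypergeometric support at fixed margins."""
    N = a + b + c + d
    K = a + c
    n1 = a + b
    lo = max(0, K - (c + d))
    hi = min(K, n1)
    supp = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(supp, N, K, n1)
    p_obs = pmf[supp == a][0]
    two = float(pmf[pmf <= p_obs * _TOL].sum())
    one = float(pmf[supp >= a].sum())
    return min(two, 1.0), min(one, 1.0)


def randomized_two_sided_p(a: int, b: int, c: int, d: int, u: float) -> float:
    """Randomized version of the two-sided Fisher P: p- + u*(p - p-),
    exactly Uniform(0,1) under the conditional null."""
    N, K, n1 = a + b + c + d, a + c, a + b
    lo = max(0, K - (c + d))
    hi = min(K, n1)
    supp = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(supp, N, K, n1)
    p_obs = pmf[supp == a][0]
    p = float(pmf[pmf <= p_obs * _TOL].sum())
    p_minus = float(pmf[pmf < p_obs / _TOL].sum())
    return p_minus + u * (p - p_minus)


def step_up_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the textbook step-up formula."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def mc_fisher_power(n1, n2, p1, p2, alpha, n_sims, seed):
    """Monte-Carlo power of the one-tailed Fisher test (vectorized over
    replicates via the hypergeometric survival function)."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1, p1, n_sims)
    x2 = rng.binomial(n2, p2, n_sims)
    pvals = stats.hypergeom.sf(x1 - 1, n1 + n2, x1 + x2, n1)
    return float(np.mean(pvals <= alpha))
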