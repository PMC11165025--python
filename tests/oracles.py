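"""Independent brute-force oracles used to validate the exact-inference engine.

Everything here deliberately avoids the package's own code paths: point
probabilities come from exact integer binomial coefficients (Fractions), the
conditional-MLE check maximises the conditional likelihood by bounded 1-D
search, and the chi-square check sums (O-E)^2/E directly.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize_scalar


def enum_fisher_p(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration in exact rational arithmetic.

    Sums hypergeometric point probabilities of every table with the observed
    margins whose probability is <= the observed table's (exact comparison,
    so ties are handled without any floating-point tolerance).
    """
    n1, K, N = a + b, a + c, a + b + c + d
    denom = math.comb(N, n1)
    lo, hi = max(0, n1 - (N - K)), min(n1, K)
    probs = {
        x: Fraction(math.comb(K, x) * math.comb(N - K, n1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def grid_cml_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional-MLE odds ratio by direct likelihood maximisation.

    Maximises the conditional log-likelihood a*log(psi) - log(sum_x w_x
    psi^x) over log(psi) with a bounded scalar optimiser; weights are exact
    integer binomial products.
    """
    n1, K, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, n1 - (N - K)), min(n1, K)
    xs = np.arange(lo, hi + 1)
    logw = np.array(
        [
            math.log(math.comb(K, x) * math.comb(N - K, n1 - x))
            for x in xs
        ]
    )

    def negloglik(t: float) -> float:
        lp = logw + xs * t
        m = lp.max()
        return -(a * t - (m + math.log(np.exp(lp - m).sum())))

    res = minimize_scalar(
        negloglik, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return math.exp(res.x)


def brute_chisq(counts) -> float:
    """Pearson chi-square by direct summation of (O-E)^2/E."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    return float(((counts - expected) ** 2 / expected).sum())


def random_tables(rng: np.random.Generator, n: int, max_margin: int = 30,
                  positive_cells: bool = False):
    """Random non-degenerate 2x2 tables with margins <= max_margin."""
    out = []
    lo = 1 if positive_cells else 0
    while len(out) < n:
        a, b, c, d = (int(v) for v in rng.integers(lo, max_margin // 2 + 1, size=4))
        N, n1, K = a + b + c + d, a + b, a + c
        if n1 == 0 or n1 == N or K == 0 or K == N:
            continue
        out.append((a, b, c, d))
    return out
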