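"""Independent brute-force oracles used to validate the statistical kernel.

These deliberately avoid the code paths they check: Fisher's exact test is
re-derived by full hypergeometric enumeration with exact rational
arithmetic, and the REML tau² estimate by direct grid search over the
restricted log-likelihood.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def reml_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model (up to const)."""
    w = 1.0 / (v + tau2)
    mu = (w * y).sum() / w.sum()
    return -0.5 * (np.log(v + tau2).sum() + np.log(w.sum()) + (w * (y - mu) ** 2).sum())


def reml_grid_search(y, v, upper: float | None = None, rounds: int = 4) -> float:
    """tau² maximizing the REML likelihood, by iteratively refined grid."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    lo = 0.0
    hi = upper if upper is not None else 10.0 * float(np.var(y)) + float(v.max()) + 1.0
    best = 0.0
    for _ in range(rounds):
        grid = np.linspace(lo, hi, 2001)
        values = [reml_loglik(t, y, v) for t in grid]
        i = int(np.argmax(values))
        best = float(grid[i])
        step = grid[1] - grid[0]
        lo, hi = max(0.0, best - step), best + step
    return best
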