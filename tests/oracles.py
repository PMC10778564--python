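"""Independent reference implementations used only to check the library.

These deliberately use elementary constructions (math.comb enumeration, the
closed-form pooled t) so they share no code path with the implementations
under test.
"""

import math
from itertools import combinations


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p by full enumeration of tables with the
    observed margins: sum of hypergeometric probabilities <= observed (with a
    small relative tolerance for float noise)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def hyper(k):
        return (
            math.comb(row1, k) * math.comb(row2, col1 - k) / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = hyper(a)
    total = 0.0
    for k in range(lo, hi + 1):
        p = hyper(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def pooled_t_p(x, y) -> float:
    """Classic equal-variance two-sample t-test p-value (closed form via the
    regularized incomplete beta function)."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    # survival of |t| under t(df) via the incomplete beta identity
    from scipy.special import betainc  # special function only, not a test

    p = betainc(df / 2, 0.5, df / (df + t * t))
    return float(p)


def rank_sum_exact_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p for small tie-free samples by complete
    enumeration of rank assignments."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(x), len(y)
    obs = sum(ranks[v] for v in x)
    mean = n * (n + m + 1) / 2
    obs_dev = abs(obs - mean)
    count = 0
    total = 0
    for combo in combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total
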