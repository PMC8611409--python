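"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the package's log-space code path: probabilities are
built from exact integer binomial coefficients (math.comb) and only converted
to float at the end.
"""

import math

TWO_SIDED_REL_TOL = 1 + 1e-7


def oracle_support_weights(N, K, n):
    """Integer hypergeometric weights over the support, plus the total."""
    lo, hi = max(0, n + K - N), min(n, K)
    ks = list(range(lo, hi + 1))
    w = [math.comb(K, k) * math.comb(N - K, n - k) for k in ks]
    return ks, w, math.comb(N, n)


def oracle_fisher_greater(a, b, c, d):
    N, K, n = a + b + c + d, a + b, a + c
    ks, w, total = oracle_support_weights(N, K, n)
    return sum(wk for k, wk in zip(ks, w) if k >= a) / total


def oracle_fisher_two_sided(a, b, c, d):
    N, K, n = a + b + c + d, a + b, a + c
    ks, w, total = oracle_support_weights(N, K, n)
    w_a = w[ks.index(a)]
    threshold = (w_a / total) * TWO_SIDED_REL_TOL
    return sum(wk for wk in w if wk / total <= threshold) / total
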