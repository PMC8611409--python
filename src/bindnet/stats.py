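"""Exact enrichment statistics on 2x2 contingency tables.

Everything downstream (pathway-pair sharing, family x compartment enrichment,
DEG-overlap validation) reduces to a hypergeometric calculation on a 2x2 table
with fixed margins, so these primitives are implemented here from first
principles rather than delegated: the hypergeometric pmf in log space (stable
to universe sizes of tens of thousands), one- and two-tailed Fisher exact
tests, and Benjamini-Hochberg / Holm p-value adjustment.

Conventions
-----------
* The table is laid out as ``a`` (in-group successes), ``b`` (in-group
  failures), ``c`` (out-group successes), ``d`` (out-group failures).
* The two-sided p-value follows the minimum-likelihood rule: sum of P(X = x)
  over all x in the support whose pmf is <= pmf(a) * (1 + 1e-7). The relative
  tolerance absorbs floating-point ties, matching the convention of the common
  reference implementations (R ``fisher.test``, ``scipy``).
* The reported odds ratio is the unconditional sample OR (a*d)/(b*c), not the
  conditional MLE; it is +inf when b*c == 0 with a*d > 0 and NaN (undefined)
  when both products vanish. An optional Haldane +0.5 correction applies to
  the OR only, never to the p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_TWO_SIDED_REL_TOL = 1 + 1e-7

# log-factorial table, grown on demand; index i holds log(i!)
_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Return the log-factorial table covering 0..n."""
    global _LOGFACT
    if n >= len(_LOGFACT):
        size = max(n + 1, 2 * len(_LOGFACT), 1024)
        _LOGFACT = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, size)))))
    return _LOGFACT


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a nonnegative integer")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_raw: float
    sidedness: str
    p_adj: float | None = None
    adjust_method: str = "none"

    @property
    def odds_ratio_defined(self) -> bool:
        return not math.isnan(self.odds_ratio)


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n), computed in log space.

    ``N`` population size, ``K`` marked items, ``n`` draws.  Out-of-support
    ``k`` returns 0.0 rather than raising.
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    lf = _logfact(N)
    log_p = (
        lf[K] - lf[k] - lf[K - k]
        + lf[N - K] - lf[n - k] - lf[N - K - n + k]
        - (lf[N] - lf[n] - lf[N - n])
    )
    return float(math.exp(log_p))


def _support_pmf(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vector of pmf values over the full support of the margins."""
    lo, hi = max(0, n + K - N), min(n, K)
    ks = np.arange(lo, hi + 1)
    lf = _logfact(N)
    log_p = (
        lf[K] - lf[ks] - lf[K - ks]
        + lf[N - K] - lf[n - ks] - lf[N - K - n + ks]
        - (lf[N] - lf[n] - lf[N - n])
    )
    return ks, np.exp(log_p)


def sample_odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    num, den = a * d, b * c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fisher_exact(
    table: ContingencyTable,
    sidedness: str = "greater",
    *,
    haldane_or: bool = False,
) -> EnrichmentResult:
    """Fisher's exact test conditioned on the table margins.

    ``sidedness`` is ``"greater"`` (P(X >= a), enrichment) or ``"two_sided"``
    (minimum-likelihood rule).  ``p_adj`` is left unset; apply
    :func:`adjust_pvalues` across the relevant test family.
    """
    if sidedness not in ("greater", "two_sided"):
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    a = table.a
    N = table.n
    K = table.a + table.b  # in-group size
    n = table.a + table.c  # successes overall
    ks, pmf = _support_pmf(N, K, n)
    if sidedness == "greater":
        # a at the support floor covers the whole distribution exactly
        p = 1.0 if a <= ks[0] else float(pmf[ks >= a].sum())
    else:
        p_a = pmf[ks == a][0]
        p = float(pmf[pmf <= p_a * _TWO_SIDED_REL_TOL].sum())
    return EnrichmentResult(
        odds_ratio=sample_odds_ratio(table, haldane=haldane_or),
        p_raw=min(p, 1.0),
        sidedness=sidedness,
    )


def adjust_pvalues(pvalues, method: str = "BH") -> list[float]:
    """Multiple-testing adjustment, returned in the input order.

    ``BH``: Benjamini-Hochberg step-up — cumulative minimum of p_(i) * m / i
    taken from the largest rank downwards.  ``Holm``: Holm-Bonferroni
    step-down — cumulative maximum of p_(i) * (m - i + 1) from the smallest
    rank upwards.  Both are capped at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    if method == "BH":
        scaled = p[order] * m / np.arange(1, m + 1)
        adj[order] = np.minimum.accumulate(scaled[::-1])[::-1]
    elif method == "Holm":
        scaled = p[order] * (m - np.arange(m))
        adj[order] = np.maximum.accumulate(scaled)
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return [float(x) for x in np.minimum(adj, 1.0)]
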