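"""Signed hypergeometric log-odds enrichment, shared by motif and cell-type
scoring.

For a cell with foreground count ``k`` out of ``n`` foreground items,
against ``K`` of ``N`` background items, the magnitude is

    | -log10( P(X >= k) / P(X <= k) ) |,   X ~ Hypergeometric(N, K, n)

and the sign follows the enrichment direction: positive when
``k/n > K/N`` (over-represented), negative when under-represented, zero
when the foreground rate equals the background rate. Tail probabilities
are computed in log space from the exact PMF so extreme cells never
underflow to +/-inf.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_LN10 = np.log(10.0)
_LOGFACT = gammaln(np.arange(1, 1002))  # ln(j!) for j = 0..1000


def _logfact(limit: int) -> np.ndarray:
    global _LOGFACT
    if limit >= _LOGFACT.size:
        _LOGFACT = gammaln(np.arange(1, 2 * limit + 2))
    return _LOGFACT


def _log_pmf_support(N: int, K: int, n: int) -> tuple[np.ndarray, int]:
    """Log-PMF of Hypergeometric(N, K, n) over its support; returns
    (log_pmf values, k_min)."""
    lf = _logfact(N + 1)
    k_min = max(0, n + K - N)
    k_max = min(n, K)
    ks = np.arange(k_min, k_max + 1)
    log_pmf = (
        lf[K] - lf[ks] - lf[K - ks]
        + lf[N - K] - lf[n - ks] - lf[N - K - n + ks]
        - (lf[N] - lf[n] - lf[N - n])
    )
    return log_pmf, k_min


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def log_odds_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Signed log10-odds enrichment of count k (of n) vs K (of N)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(
            f"invalid hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    if n == 0 or N == 0:
        return 0.0
    log_pmf, k_min = _log_pmf_support(N, K, n)
    i = k - k_min
    if i < 0:  # k below support: impossible under the model
        raise ValueError(f"count k={k} below hypergeometric support")
    log_sf_incl = _logsumexp(log_pmf[i:])   # log P(X >= k)
    log_cdf = _logsumexp(log_pmf[:i + 1])   # log P(X <= k)
    magnitude = abs((log_sf_incl - log_cdf) / _LN10)
    direction = (k * N > K * n) - (k * N < K * n)  # sign of k/n - K/N
    return direction * magnitude
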