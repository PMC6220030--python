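"""Cross-dataset concordance: hypergeometric list overlap and binomial replication.

Both tests are exact upper tails accumulated in log space (log-gamma based
log-pmfs combined with logsumexp), so probabilities far below the floating
underflow threshold remain comparable through their log10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = ["OverlapTest", "ReplicationTest", "hypergeometric_overlap", "binomial_replication"]

_LOG10 = np.log(10.0)


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of the overlap between two gene lists."""

    N: int  # universe size
    K: int  # first list size
    n: int  # second list size
    k: int  # observed overlap
    p: float  # P(X >= k)
    log10_p: float


@dataclass(frozen=True)
class ReplicationTest:
    """Upper-tail binomial test that k of n primary findings replicate."""

    n: int
    k: int
    p0: float
    p: float  # P(X >= k)
    log10_p: float


def _log_upper_tail(logpmf: np.ndarray) -> tuple[float, float]:
    log_p = float(logsumexp(logpmf))
    log_p = min(log_p, 0.0)  # guard against rounding above 1
    return float(np.exp(log_p)), log_p / _LOG10


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> OverlapTest:
    """P(X >= k) for the overlap of a K-list and an n-list in an N universe."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    upper = min(K, n)
    support = np.arange(k, upper + 1)
    if len(support) == 0 or k == 0:
        return OverlapTest(N=N, K=K, n=n, k=k, p=1.0, log10_p=0.0)
    logpmf = stats.hypergeom.logpmf(support, N, K, n)
    p, log10_p = _log_upper_tail(logpmf)
    return OverlapTest(N=N, K=K, n=n, k=k, p=p, log10_p=log10_p)


def binomial_replication(k: int, n: int, p0: float) -> ReplicationTest:
    """P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"inconsistent counts: k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"null replication probability must be in (0,1): {p0}")
    if k == 0:
        return ReplicationTest(n=n, k=k, p0=p0, p=1.0, log10_p=0.0)
    support = np.arange(k, n + 1)
    logpmf = stats.binom.logpmf(support, n, p0)
    p, log10_p = _log_upper_tail(logpmf)
    return ReplicationTest(n=n, k=k, p0=p0, p=p, log10_p=log10_p)
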