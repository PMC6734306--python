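"""One-sided hypergeometric exact test with mid-p correction.

Conditioning on the margins of the 2x2 table (N classifiable days, K of them
in menstrual windows, n attack onsets, k of those in windows), the number of
in-window onsets under the null hypothesis of no menstrual modulation
(``delta_mu = mu_M - mu_NM = 0``) is hypergeometric.  The reported value is
the one-sided upper tail

    p = sum_{i=k}^{min(n,K)} f_HG(i; K, n, N) - 1/2 * f_HG(k; K, n, N),

i.e. Fisher's exact one-sided p with the mid-p correction, which removes the
conservatism induced by the discreteness of the table (n itself is random
before the diary is observed).  Only the upper tail is tested: the criterion
looks for an *elevated* onset probability inside the windows, and a two-sided
test would be needlessly conservative.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .trimming import ContingencyCounts


@dataclass(frozen=True)
class MidPValue:
    """A mid-p value with its source table.

    ``evaluable`` is False when the table carries no information about the
    within/outside contrast (no days, no window days, or nothing but window
    days); no numeric p is produced in that case.
    """

    p: float | None
    counts: ContingencyCounts
    evaluable: bool

    def __float__(self) -> float:
        if not self.evaluable:
            raise ValueError("mid-p value not evaluable for this table")
        return self.p


def _check_sizes(k: int, K: int, n: int, N: int) -> None:
    if min(k, K, n, N) < 0:
        raise ValueError("hypergeometric arguments must be non-negative")
    if K > N or n > N:
        raise ValueError(f"inconsistent table sizes: K={K}, n={n}, N={N}")


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n): C(K,k) C(N-K,n-k) / C(N,n).

    Arguments outside the support return 0; impossible table sizes (``K > N``
    or ``n > N``) raise ``ValueError``.  Evaluated in log-space, exact to
    floating precision.
    """
    _check_sizes(k, K, n, N)
    if k > min(n, K) or n - k > N - K:
        return 0.0
    return float(hypergeom.pmf(k, N, K, n))


def upper_tail_p(counts: ContingencyCounts) -> float:
    """Plain (uncorrected) one-sided upper-tail probability P(X >= k).

    Diagnostic only; the diagnosis path always applies the mid-p correction.
    """
    return float(hypergeom.sf(counts.k - 1, counts.N, counts.K, counts.n))


def midp_value(counts: ContingencyCounts) -> MidPValue:
    """One-sided upper-tail mid-p value for a contingency table.

    Not evaluable when ``N == 0``, ``K == 0`` or ``K == N``.  Otherwise
    ``0 < p < 1``.
    """
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    if N == 0 or K == 0 or K == N:
        return MidPValue(None, counts, evaluable=False)
    tail = float(hypergeom.sf(k - 1, N, K, n))
    point = hypergeom_pmf(k, K, n, N)
    p = tail - 0.5 * point
    # guard against floating drift at the extremes of the open interval
    p = min(max(p, 5e-324), 1.0 - 1e-16)
    return MidPValue(p, counts, evaluable=True)
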