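"""Shared statistical primitives: binomial upper tail and BH adjustment."""

from __future__ import annotations

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests


def binom_upper_tail(k: float, n: float, p: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p).

    Generalized to real-valued ``k`` and ``n`` (background-corrected counts
    are fractional) through the regularized incomplete beta function:
    ``P(X >= k) = I_p(k, n - k + 1)``.  For integer inputs this equals the
    exact sum of binomial point masses from ``k`` to ``n``.

    Parameters
    ----------
    k, n
        Corrected counts, ``0 <= k <= n``.
    p
        Per-trial success probability.

    Raises
    ------
    ValueError
        If ``p`` is outside [0, 1] or ``k > n`` or ``k < 0``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k > n:
        raise ValueError(f"k must be <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(special.betainc(k, n - k + 1.0, p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1.

    Raises
    ------
    ValueError
        If any input is outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
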