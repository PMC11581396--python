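"""Group-level inference for encoding-model comparisons.

Wilcoxon signed-rank tests on paired scalp-average accuracies use the
normal approximation without continuity correction and with the standard
midrank tie variance correction, reporting a signed Z (positive when the
first sample dominates).  This convention makes the all-positive case at
n = 19 hit its exact maximum Z = 95 / sqrt(617.5) = 3.8230.  An
exact-enumeration mode is available for small n.  Electrode-wise p-values
are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "signed_rank",
    "z_to_p",
    "fdr_bh",
    "binomial_tail",
    "binomial_cdf",
    "spearman",
]


@dataclass
class StatResult:
    statistic: float   # signed Z
    p: float
    n: int
    tails: int
    corrected_p: float | None = None


def z_to_p(z: float, tails: int = 2) -> float:
    """Normal tail probability: ``tails * (1 - Phi(|Z|))``, capped at 1."""
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    return float(min(tails * sps.norm.sf(abs(z)), 1.0))


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray, tails: int) -> float:
    """Enumerate all 2^n sign patterns of the given ranks."""
    n = ranks.size
    ws = np.array([np.sum(ranks[np.array(signs, dtype=bool)])
                   for signs in product((0, 1), repeat=n)])
    if tails == 1:
        return float(np.mean(ws >= w_plus))
    lo = float(np.mean(ws <= w_plus))
    hi = float(np.mean(ws >= w_plus))
    return float(min(2 * min(lo, hi), 1.0))


def signed_rank(x, y=None, tails: int = 2, method: str = "normal") -> StatResult:
    """Wilcoxon signed-rank test on paired differences.

    Parameters
    ----------
    x, y : array-like
        Paired samples (the test is on ``x - y``), or a single vector of
        differences when ``y`` is None.
    tails : {1, 2}
        One-tail tests the alternative ``x > y``.
    method : {"normal", "exact", "auto"}
        "normal" is the tie-corrected normal approximation (no continuity
        correction); "exact" enumerates sign patterns (n <= 12); "auto"
        picks exact for n <= 12 and the normal approximation above.
    """
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]  # standard zero-difference exclusion
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero (degenerate)")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts.astype(float) ** 3 - counts) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise ValueError("zero variance (all ranks tied away)")
    z = (w_plus - mu) / np.sqrt(sigma2)
    if method == "auto":
        method = "exact" if n <= 12 else "normal"
    if method == "exact":
        if n > 12:
            raise ValueError("exact enumeration limited to n <= 12")
        p = _signed_rank_exact_p(w_plus, ranks, tails)
    elif method == "normal":
        if n < 5:
            raise ValueError("normal approximation needs n >= 5")
        p = z_to_p(z, tails) if tails == 2 else float(min(sps.norm.sf(z), 1.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult(float(z), p, n, tails)


def fdr_bh(pvals, q: float = 0.05, method: str = "bh") -> tuple:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted_p, reject_mask)``; adjusted p-values are monotone
    nondecreasing in raw-p order.  ``method="by"`` applies the
    Benjamini-Yekutieli factor for arbitrary dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method == "by":
        ranked *= np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError(f"unknown method {method!r}")
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


def binomial_tail(n: int, k: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), computed stably (log-space sf)."""
    if k <= 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


def binomial_cdf(n: int, k: int, p0: float) -> float:
    """P(X <= k); complements :func:`binomial_tail` at k+1."""
    return float(sps.binom.cdf(k, n, p0))


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of tie-averaged ranks."""
    return float(sps.spearmanr(x, y).statistic)
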