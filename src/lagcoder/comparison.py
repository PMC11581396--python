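"""Union models, predicted-variance partitioning and layer-depth trends.

A union model concatenates feature sets column-wise and is fit jointly; a
feature set's unique contribution at an electrode is estimated as the
square root of the (clipped nonnegative) difference between the union's
and the reduced model's squared held-out correlations -- a
pseudo-correlation on the same scale as r.  Pairwise partitions further
split the union's predicted variance into shared and unique percentages.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import FeatureSeries
from .stats import signed_rank, spearman

__all__ = [
    "union_features",
    "unique_partition",
    "shared_fraction",
    "layer_depth_trend",
]


def union_features(fs_list: list, name: str | None = None) -> FeatureSeries:
    """Column-wise concatenation of aligned feature series.

    Per-part provenance (name, column span) is retained in ``meta``.
    """
    if not fs_list:
        raise ValueError("union of zero feature sets")
    n_times = {f.n_times for f in fs_list}
    if len(n_times) != 1:
        raise ValueError(f"length mismatch across parts: {sorted(n_times)}")
    rates = {f.fs for f in fs_list}
    if len(rates) != 1:
        raise ValueError(f"sampling-rate mismatch across parts: {sorted(rates)}")
    data = np.concatenate([f.data for f in fs_list], axis=1)
    parts, col = [], 0
    for f in fs_list:
        parts.append({"name": f.name, "cols": [col, col + f.n_features]})
        col += f.n_features
    name = name or "[" + " ".join(f.name for f in fs_list) + "]"
    return FeatureSeries(name, data, fs_list[0].fs, fs_list[0].run_id,
                         {"parts": parts})


def unique_partition(r_union, r_subset) -> np.ndarray:
    """Pseudo-correlation sqrt(max(r_union^2 - r_subset^2, 0)), elementwise.

    Negative partitions (possible under overfitting) are zeroed.
    """
    r_union = np.asarray(r_union, dtype=float)
    r_subset = np.asarray(r_subset, dtype=float)
    return np.sqrt(np.clip(r_union ** 2 - r_subset ** 2, 0.0, None))


def shared_fraction(r_a: float, r_b: float, r_union: float) -> tuple:
    """Percentage split of the union's predicted variance.

    shared = 100 (r_a^2 + r_b^2 - r_U^2) / r_U^2 and each model's unique
    share is its own r^2 minus the shared variance, as a percentage of the
    union's r^2; the three percentages sum to 100 algebraically.  Negative
    shared estimates are reported as-is with a warning (only electrode-wise
    unique pseudo-correlations are clipped, not these scalars).
    """
    ra2, rb2, ru2 = float(r_a) ** 2, float(r_b) ** 2, float(r_union) ** 2
    if ru2 == 0:
        warnings.warn("union accuracy is 0; shared fraction undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    shared = 100.0 * (ra2 + rb2 - ru2) / ru2
    if shared < 0:
        warnings.warn(f"negative shared-variance estimate ({shared:.2f}%)",
                      RuntimeWarning, stacklevel=2)
    unique_a = 100.0 * ra2 / ru2 - shared
    unique_b = 100.0 * rb2 / ru2 - shared
    return shared, unique_a, unique_b


def layer_depth_trend(accuracies: np.ndarray, tails: int = 2) -> tuple:
    """Per-subject Spearman rho of accuracy vs layer index, then a group
    signed-rank test of the rho values against zero.

    Parameters
    ----------
    accuracies : ndarray (n_subjects, n_layers)
        Scalp-average accuracy per subject and layer (depth 0..L-1).

    Returns
    -------
    rhos : ndarray (n_subjects,)
    stat : StatResult with the group signed-rank Z and p.
    """
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    depth = np.arange(acc.shape[1], dtype=float)
    rhos = np.array([spearman(depth, row) for row in acc])
    return rhos, signed_rank(rhos, tails=tails)
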