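"""Independent brute-force reference implementations used by the tests.

These oracles deliberately avoid the package's code paths: percentiles via
O(n^2) pairwise comparisons, level stratification via an explicit
sort-and-partition, and C1 pooling via naive nested-loop windowed maxima.
"""

import numpy as np

EXCLUDED = "excluded"


def brute_force_percentiles(values):
    """O(n^2) pairwise-comparison rank oracle."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.empty(n)
    for k, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        avg_rank = less + (equal + 1) / 2.0
        out[k] = (avg_rank - 1) / (n - 1)
    return out


def oracle_stratify(percentiles, min_gap=0.1):
    """Exhaustive sort-and-partition reference for one category's 6 pairs."""
    order = np.argsort(percentiles, kind="stable")
    labels = np.empty(6, dtype=object)
    for rank, idx in enumerate(order):
        labels[idx] = ["high", "high", "medium", "medium", "low", "low"][rank]
    sorted_vals = np.asarray(percentiles)[order]
    for b in (1, 3):
        if sorted_vals[b + 1] - sorted_vals[b] < min_gap:
            labels[order[b]] = EXCLUDED
            labels[order[b + 1]] = EXCLUDED
    return labels


def naive_windowed_max(arr, size, stride):
    """Nested-loop windowed maximum with truncated edge windows."""
    h, w = arr.shape
    rows = list(range(0, h, stride)) if h > size else [0]
    cols = list(range(0, w, stride)) if w > size else [0]
    out = np.empty((len(rows), len(cols)))
    for a, r in enumerate(rows):
        for b, c in enumerate(cols):
            best = -np.inf
            for rr in range(r, min(r + size, h)):
                for cc in range(c, min(c + size, w)):
                    best = max(best, arr[rr, cc])
            out[a, b] = best
    return out
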