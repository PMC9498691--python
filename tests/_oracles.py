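"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's estimation code paths: the segmented
fit is checked against an exhaustive profile scan with plain OLS at each
candidate knot, and the matching distance against direct arithmetic.
"""

import numpy as np


def grid_search_knot(times, values, psi_grid):
    """Exhaustive single-knot search: OLS of y on {1, t, (t-psi)+} at every
    candidate knot; returns (best_psi, best_rss)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    best_rss, best_psi = np.inf, None
    for psi in psi_grid:
        X = np.column_stack([np.ones_like(t), t, np.clip(t - psi, 0.0, None)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        rss = float(r @ r)
        if rss < best_rss:
            best_rss, best_psi = rss, float(psi)
    return best_psi, best_rss


def rss_at_knot(times, values, psi):
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(t), t, np.clip(t - psi, 0.0, None)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def euclidean_match_distance(a, b, ranges):
    """Direct arithmetic version of the range-normalized match distance."""
    return sum(((a[k] - b[k]) / ranges[k]) ** 2 for k in ranges) ** 0.5
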