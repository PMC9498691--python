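"""Single-knot segmented regression and biomarker ordering.

Each biomarker's evolution on the conversion-anchored time scale is
summarized by a one-knot linear spline

    y = a + b1 * t + (b2 - b1) * (t - psi)_+ + eps,   eps ~ N(0, sigma^2),

whose breakpoint ``psi`` marks the biomarker's inflection.  The knot is
estimated by iterative linearization: given a working knot psi_i, regress y
on {1, t, (t - psi_i)_+, -1[t > psi_i]} and update
psi_{i+1} = psi_i + gamma_hat / delta_hat, where delta_hat is the
slope-difference coefficient and gamma_hat the indicator coefficient (which
vanishes at the solution).  Convergence is |delta psi| < 0.01 months; a
non-convergent start triggers a multi-start over a grid of initial knots and
the minimum-objective fit is reported.  With Gaussian errors the objective
(negative log-likelihood) is a monotone function of the residual sum of
squares.

Sorting the converged, conclusive fits by knot yields the biomarkers'
temporal ordering; the trend classifier separates knots that mark a
variable beginning to stabilize (post-knot slope smaller in magnitude) from
ones beginning to destabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FitOptions",
    "SegmentedFit",
    "remove_outliers_iqr",
    "mean_curve",
    "fit_segmented",
    "fit_biomarker",
    "classify_trend",
    "order_biomarkers",
    "overlay_normalize",
]


@dataclass(frozen=True)
class FitOptions:
    """Tunables of the segmented fit.

    The knot is constrained to the [5th, 95th] percentile window of the
    observed times, additionally requiring ``min_per_segment`` observations
    strictly on each side; knots pushed against those limits are the
    signature of trend-free data and are classified inconclusive.
    """

    min_points: int = 20
    min_per_segment: int = 10
    window_quantiles: tuple[float, float] = (0.05, 0.95)
    tol: float = 0.01  # months
    max_iter: int = 100
    n_starts: int = 10
    alpha: float = 0.05
    #: fraction of the time range at each end where a knot is inconclusive
    edge_fraction: float = 0.10


@dataclass(frozen=True)
class SegmentedFit:
    """Result of a single-knot segmented regression for one variable."""

    variable: str
    knot: float
    knot_se: float
    intercept: float
    intercept_se: float
    slope_pre: float
    slope_pre_se: float
    slope_post: float
    slope_post_se: float
    slope_diff: float
    slope_diff_se: float
    slope_pre_p: float
    slope_post_p: float
    slope_diff_p: float
    n_points: int
    n_pre: int
    n_post: int
    converged: bool
    objective: float  # negative log-likelihood at the optimum
    trend: str  # stabilizing | destabilizing | inconclusive
    t_min: float
    t_max: float


def remove_outliers_iqr(values) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier exclusion.

    Keeps values inside the closed interval
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR], with quartiles by linear interpolation.
    Fewer than 4 finite values: nothing is filtered and a warning is issued.
    Returns ``(kept, removed)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4:
        warnings.warn(
            f"only {len(v)} finite values; IQR filter skipped", stacklevel=2
        )
        return v, np.array([], dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


def _iqr_mask(values: np.ndarray) -> np.ndarray:
    """Boolean keep-mask version of the Tukey fences (NaN-safe, False for
    non-finite entries)."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        return finite
    q1, q3 = np.percentile(v[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return finite & (v >= lo) & (v <= hi)


def mean_curve(times, values, min_n: int = 5) -> pd.DataFrame:
    """Mean-value curve over adjusted time.

    One row per unique time with the mean value and measurement count;
    points backed by fewer than ``min_n`` measurements are flagged
    ``suppressed`` (they are plotted as gaps, mirroring the display rule
    for noisy extremes).
    """
    df = pd.DataFrame({"adjusted_months": times, "value": values}).dropna()
    g = df.groupby("adjusted_months")["value"].agg(["mean", "count"]).reset_index()
    g.columns = ["adjusted_months", "mean_value", "n_measurements"]
    g["suppressed"] = g["n_measurements"] < min_n
    return g


def _design(t: np.ndarray, psi: float) -> np.ndarray:
    u = np.clip(t - psi, 0.0, None)
    v = -(t > psi).astype(float)
    return np.column_stack([np.ones_like(t), t, u, v])


def _window(t: np.ndarray, opts: FitOptions) -> tuple[float, float]:
    lo_q, hi_q = np.quantile(t, opts.window_quantiles)
    ts = np.sort(t)
    lo_n = ts[opts.min_per_segment - 1]  # >= min_per_segment points at/below psi
    hi_n = ts[-(opts.min_per_segment + 1)]  # > min_per_segment points above psi
    return max(lo_q, lo_n), min(hi_q, hi_n)


def _iterate(t, y, psi0, lo, hi, opts) -> tuple[float, bool]:
    """Run the linearized update from one start; returns (psi, converged).

    Updates that overshoot (grow instead of contract) are damped by halving,
    which tames the oscillation the raw update exhibits when the breakpoint
    sits near the edge of the data.
    """
    psi = float(np.clip(psi0, lo, hi))
    hits = 0
    prev_step = np.inf
    for _ in range(opts.max_iter):
        X = _design(t, psi)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        delta, gamma = coef[2], coef[3]
        if abs(delta) < 1e-12:
            return psi, False
        step = gamma / delta
        halvings = 0
        while abs(step) > prev_step and halvings < 8:
            step *= 0.5
            halvings += 1
        new = psi + step
        if new < lo or new > hi:
            new = float(np.clip(new, lo, hi))
            hits += 1
            if hits > 5:
                return new, False
        if abs(new - psi) < opts.tol:
            return new, True
        prev_step = abs(new - psi)
        psi = new
    return psi, False


def _rss(t, y, psi) -> float:
    X = np.column_stack([np.ones_like(t), t, np.clip(t - psi, 0.0, None)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _segment_counts(t, psi) -> tuple[int, int]:
    return int(np.sum(t <= psi)), int(np.sum(t > psi))


def fit_segmented(times, values, variable: str = "", opts: FitOptions | None = None) -> SegmentedFit:
    """Fit the one-knot linear spline to raw observations.

    Expects outlier-filtered data (see :func:`fit_biomarker` for the
    composed convenience).  Non-convergence from the default start triggers
    a multi-start over ``n_starts`` knot positions spanning the allowed
    window; among converged candidates the minimum-RSS fit wins.  If no
    admissible interior knot exists the fit is returned non-converged with
    trend ``inconclusive``.
    """
    opts = opts or FitOptions()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(t)
    if n < opts.min_points:
        return _failed_fit(variable, n, t)
    lo, hi = _window(t, opts)
    if not lo < hi:
        return _failed_fit(variable, n, t)

    # Multi-start: the RSS profile in psi is piecewise-smooth with local
    # minima, so the linearized iteration runs from a grid of initial knots
    # (median first) and the minimum-objective convergent fit is reported.
    candidates: list[tuple[float, float]] = []  # (rss, psi)
    starts = [float(np.median(t))]
    starts += list(np.linspace(lo, hi, opts.n_starts + 2)[1:-1])
    # seed two extra starts at the best knots of a coarse profile scan, so
    # a breakpoint close to the data edge still gets a nearby start
    coarse = np.arange(np.ceil(lo), hi, 1.0)
    prof = None
    if len(coarse) > 2:
        prof = np.array([_rss(t, y, p) for p in coarse])
        starts += list(coarse[np.argsort(prof)[:2]])
    for psi0 in starts:
        psi, conv = _iterate(t, y, psi0, lo, hi, opts)
        if conv and _admissible(t, psi, lo, hi, opts):
            candidates.append((_rss(t, y, psi), psi))
    # The RSS profile is kinked at the observed times; a minimum sitting in
    # such a kink repels the gradient-style update.  When the profile scan
    # strictly beats every iterative candidate, its argmin is the estimate.
    if prof is not None:
        j = int(np.argmin(prof))
        if _admissible(t, coarse[j], lo, hi, opts) and (
            not candidates or prof[j] < min(candidates)[0] - 1e-9
        ):
            candidates.append((float(prof[j]), float(coarse[j])))
    if not candidates:
        return _failed_fit(variable, n, t)

    _, psi_hat = min(candidates, key=lambda c: c[0])
    return _finalize(t, y, psi_hat, variable, opts)


def _admissible(t, psi, lo, hi, opts) -> bool:
    if not (lo <= psi <= hi):
        return False
    n_pre, n_post = _segment_counts(t, psi)
    return n_pre >= opts.min_per_segment and n_post >= opts.min_per_segment


def _failed_fit(variable: str, n: int, t: np.ndarray) -> SegmentedFit:
    nan = float("nan")
    t_min = float(t.min()) if len(t) else nan
    t_max = float(t.max()) if len(t) else nan
    return SegmentedFit(
        variable=variable, knot=nan, knot_se=nan, intercept=nan, intercept_se=nan,
        slope_pre=nan, slope_pre_se=nan, slope_post=nan, slope_post_se=nan,
        slope_diff=nan, slope_diff_se=nan, slope_pre_p=nan, slope_post_p=nan,
        slope_diff_p=nan, n_points=n, n_pre=0, n_post=0, converged=False,
        objective=nan, trend="inconclusive", t_min=t_min, t_max=t_max,
    )


def _finalize(t, y, psi, variable, opts) -> SegmentedFit:
    n = len(t)
    # final model: y = a + b1 t + delta (t - psi)_+ ; SEs from this design
    X3 = np.column_stack([np.ones_like(t), t, np.clip(t - psi, 0.0, None)])
    res = sm.OLS(y, X3).fit()
    a, b1, delta = res.params
    cov = res.cov_params()
    b2 = b1 + delta
    b2_se = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]))
    dof = max(n - 4, 1)
    rss = float(res.ssr)
    sigma2 = rss / n
    nll = 0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)

    # knot SE from the linearized (4-column) design at the optimum:
    # Var(psi_hat) ~= Var(gamma_hat) / delta_hat^2
    X4 = _design(t, psi)
    res4 = sm.OLS(y, X4).fit()
    knot_se = float(res4.bse[3] / abs(delta)) if abs(delta) > 1e-12 else float("nan")

    def pval(est, se):
        if not np.isfinite(se) or se == 0:
            return float("nan")
        return float(2.0 * stats.t.sf(abs(est / se), dof))

    n_pre, n_post = _segment_counts(t, psi)
    fit = SegmentedFit(
        variable=variable,
        knot=float(psi),
        knot_se=knot_se,
        intercept=float(a),
        intercept_se=float(res.bse[0]),
        slope_pre=float(b1),
        slope_pre_se=float(res.bse[1]),
        slope_post=float(b2),
        slope_post_se=b2_se,
        slope_diff=float(delta),
        slope_diff_se=float(res.bse[2]),
        slope_pre_p=pval(b1, res.bse[1]),
        slope_post_p=pval(b2, b2_se),
        slope_diff_p=pval(delta, res.bse[2]),
        n_points=n,
        n_pre=n_pre,
        n_post=n_post,
        converged=True,
        objective=float(nll),
        trend="inconclusive",
        t_min=float(t.min()),
        t_max=float(t.max()),
    )
    return _with_trend(fit, classify_trend(fit, opts.alpha))


def _with_trend(fit: SegmentedFit, trend: str) -> SegmentedFit:
    d = vars(fit).copy()
    d["trend"] = trend
    return SegmentedFit(**d)


def fit_biomarker(times, values, variable: str = "", opts: FitOptions | None = None) -> SegmentedFit:
    """Drop missing values, apply the IQR outlier filter (globally per
    variable), then fit the segmented model."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    keep = _iqr_mask(y)
    return fit_segmented(t[keep], y[keep], variable=variable, opts=opts)


def classify_trend(fit: SegmentedFit, alpha: float = 0.05) -> str:
    """Interpret the knot: stabilizing, destabilizing, or inconclusive.

    Stabilizing: the post-knot slope is significantly smaller in magnitude
    than the pre-knot slope (the variable flattens); destabilizing: larger.
    Inconclusive when neither slope differs from zero at level ``alpha``,
    the slope change itself is not significant, or the knot falls in the
    outer 10% of the observed time range (where data are too sparse to
    trust, the visual discard rule for trend-free variables).
    """
    if not fit.converged or not np.isfinite(fit.knot):
        return "inconclusive"
    t_range = fit.t_max - fit.t_min
    edge = 0.10 * t_range
    if fit.knot < fit.t_min + edge or fit.knot > fit.t_max - edge:
        return "inconclusive"
    slopes_zero = (
        (not np.isfinite(fit.slope_pre_p) or fit.slope_pre_p >= alpha)
        and (not np.isfinite(fit.slope_post_p) or fit.slope_post_p >= alpha)
    )
    if slopes_zero:
        return "inconclusive"
    if not np.isfinite(fit.slope_diff_p) or fit.slope_diff_p >= alpha:
        return "inconclusive"
    return "stabilizing" if abs(fit.slope_post) < abs(fit.slope_pre) else "destabilizing"


def order_biomarkers(fits) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Temporal ordering of biomarkers by knot position.

    Converged, conclusive fits are sorted by knot ascending (earliest
    inflection first); inconclusive or non-converged fits are listed
    separately.  Returns ``(ordered, excluded)``.
    """
    rows = [vars(f) for f in fits]
    df = pd.DataFrame(rows)
    cols = ["variable", "knot", "knot_se", "slope_pre", "slope_post", "trend",
            "n_points", "converged"]
    usable = df[df["converged"] & (df["trend"] != "inconclusive")]
    ordered = usable.sort_values("knot", kind="mergesort")[cols].reset_index(drop=True)
    excluded = df[~(df["converged"] & (df["trend"] != "inconclusive"))][cols].reset_index(drop=True)
    return ordered, excluded


def overlay_normalize(curves: dict) -> dict:
    """Rescale curves to [0, 1], all increasing, for a single-panel overlay.

    ``curves`` maps name -> (times, values).  Decreasing curves (negative
    overall linear trend) are sign-flipped before the affine [0, 1] mapping,
    so every curve reads as "abnormality rising over time".  A constant
    curve has no direction and is rejected.  Idempotent.
    """
    out = {}
    for name, (t, v) in curves.items():
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"curve {name!r} is constant; cannot normalize")
        slope = np.polyfit(t, v, 1)[0]
        if slope < 0:
            v = -v
        v = (v - v.min()) / (v.max() - v.min())
        out[name] = (t, v)
    return out
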