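"""Event-anchored longitudinal alignment and its validation.

Heterogeneous visit timelines are re-referenced to each subject's MCI-to-AD
conversion: the first visit carrying an AD diagnosis after an MCI visit
becomes adjusted time 0, and every other visit shifts rigidly with it.
Subjects who never convert ("static" subjects) borrow an anchor by hot-deck
nearest-neighbor imputation: their comparison visit (last visit for
static-MCI, baseline for static-AD) is matched against every converter
visit on MMSE, ADNI-MEM and age (range-normalized Euclidean distance) and
receives the best match's adjusted time.

The imputation is validated by rebuilding the time variable many times with
the donor drawn uniformly from the top-k matches, then comparing each
replicate's adjusted-time distribution with the original by a two-sample
Kolmogorov--Smirnov test whose p-value comes from pooled bootstrap
resampling (robust to the heavy ties that rigid shifts produce).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnomalousTimelineError",
    "ImputationError",
    "MatchConfig",
    "classify_subject",
    "adjust_converter",
    "match_distance",
    "impute_static_anchor",
    "build_adjusted_times",
    "build_replicates",
    "ks_statistic",
    "ks_validate",
    "ks_summary",
]

logger = logging.getLogger(__name__)

MAP_COLUMNS = [
    "rid", "viscode_months", "adjusted_months", "anchor_source",
    "donor_rid", "donor_visit", "replicate_id",
]


class AnomalousTimelineError(ValueError):
    """Diagnosis sequence fits no class (e.g. AD-to-MCI reversion without a
    later conversion, or mixed stages that never reach AD)."""


class ImputationError(ValueError):
    """Static-subject anchor cannot be imputed (empty donor pool or missing
    matching covariates at the comparison visit)."""


@dataclass(frozen=True)
class MatchConfig:
    """Configuration of the nearest-neighbor time imputation.

    ``ranges`` maps each matching variable to its normalization range; when
    ``None`` the observed min--max over the donor pool is used (frozen once
    per run and reported in the output metadata).
    """

    match_vars: tuple[str, ...] = ("mmse", "adni_mem", "age")
    ranges: Mapping[str, float] | None = None
    k: int = 5
    n_replicates: int = 1000
    seed: int = 0


def classify_subject(timeline: pd.DataFrame) -> str:
    """Classify one subject's timeline as converter / static_MCI / static_AD.

    A converter has an MCI visit strictly before an AD visit.  A static
    subject holds a single diagnosis throughout.  Anything else (including
    an all-NL timeline, which the cohort filter removes upstream) raises
    :class:`AnomalousTimelineError`.
    """
    tl = timeline.sort_values("viscode_months")
    diag = tl["diagnosis"].tolist()
    if not diag:
        raise AnomalousTimelineError("timeline has no visits")
    seen_mci = False
    for d in diag:
        if d == "MCI":
            seen_mci = True
        elif d == "AD" and seen_mci:
            return "converter"
    uniq = set(diag)
    if uniq == {"MCI"}:
        return "static_MCI"
    if uniq == {"AD"}:
        return "static_AD"
    raise AnomalousTimelineError(f"unclassifiable diagnosis sequence {diag}")


def _first_conversion_visit(timeline: pd.DataFrame) -> int:
    tl = timeline.sort_values("viscode_months")
    seen_mci = False
    for _, row in tl.iterrows():
        if row["diagnosis"] == "MCI":
            seen_mci = True
        elif row["diagnosis"] == "AD" and seen_mci:
            return int(row["viscode_months"])
    raise AnomalousTimelineError("no MCI-to-AD conversion in timeline")


def _rigid_rows(
    timeline: pd.DataFrame,
    anchor_visit: int,
    anchor_adjusted: int,
    source: str,
    donor_rid=None,
    donor_visit=None,
    replicate_id: int = 0,
) -> pd.DataFrame:
    rid = timeline["rid"].iloc[0]
    rows = [
        {
            "rid": rid,
            "viscode_months": int(v),
            "adjusted_months": int(v) - anchor_visit + anchor_adjusted,
            "anchor_source": source,
            "donor_rid": donor_rid,
            "donor_visit": donor_visit,
            "replicate_id": replicate_id,
        }
        for v in sorted(timeline["viscode_months"])
    ]
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


def adjust_converter(timeline: pd.DataFrame) -> pd.DataFrame:
    """Re-reference a converter's visits to the first AD visit (adjusted 0).

    A subject first diagnosed AD at month 24 gets baseline at -24 and the
    36-month visit at +12.
    """
    anchor = _first_conversion_visit(timeline)
    return _rigid_rows(timeline, anchor, 0, "self")


def match_distance(a: Mapping, b: Mapping, ranges: Mapping[str, float]) -> float:
    """Range-normalized Euclidean distance between two visits over the
    matching variables (the keys of ``ranges``)."""
    total = 0.0
    for var, rng in ranges.items():
        if rng <= 0:
            raise ValueError(f"range for {var} must be positive")
        total += ((float(a[var]) - float(b[var])) / rng) ** 2
    return float(np.sqrt(total))


def _donor_distances(
    query: Mapping, donor_pool: pd.DataFrame, ranges: Mapping[str, float]
) -> pd.DataFrame:
    d = np.zeros(len(donor_pool))
    for var, rng in ranges.items():
        if rng <= 0:
            raise ValueError(f"range for {var} must be positive")
        d += ((donor_pool[var].to_numpy(float) - float(query[var])) / rng) ** 2
    out = donor_pool.copy()
    out["_distance"] = np.sqrt(d)
    # deterministic tie-break: distance, then donor rid, then donor visit
    return out.sort_values(
        ["_distance", "rid", "viscode_months"], kind="mergesort"
    ).reset_index(drop=True)


def impute_static_anchor(
    timeline: pd.DataFrame,
    donor_pool: pd.DataFrame,
    ranges: Mapping[str, float],
    rank_policy: str = "best",
    k: int = 5,
    rng: np.random.Generator | None = None,
    subject_class: str | None = None,
    replicate_id: int = 0,
) -> pd.DataFrame:
    """Impute a conversion anchor for one static subject.

    The comparison visit -- last visit for static-MCI, baseline for
    static-AD -- receives the selected donor visit's adjusted time; all
    other visits shift rigidly.  ``rank_policy`` is ``"best"`` (the original
    run) or ``"topk"`` (uniform among the k closest donors; replicate runs).

    ``donor_pool`` must carry the matching variables plus ``rid``,
    ``viscode_months`` and ``adjusted_months`` for every converter visit.
    """
    if donor_pool.empty:
        raise ImputationError("donor pool is empty")
    cls = subject_class or classify_subject(timeline)
    tl = timeline.sort_values("viscode_months")
    query_row = tl.iloc[-1] if cls == "static_MCI" else tl.iloc[0]
    if any(pd.isna(query_row.get(v)) for v in ranges):
        raise ImputationError(
            f"subject {query_row['rid']}: matching covariates missing at the "
            "comparison visit"
        )
    ranked = _donor_distances(query_row, donor_pool, ranges)
    if rank_policy == "best":
        sel = ranked.iloc[0]
    elif rank_policy == "topk":
        if rng is None:
            raise ValueError("rank_policy='topk' needs an rng")
        sel = ranked.iloc[int(rng.integers(0, min(k, len(ranked))))]
    else:
        raise ValueError(f"unknown rank_policy {rank_policy!r}")
    anchor_visit = int(query_row["viscode_months"])
    return _rigid_rows(
        tl,
        anchor_visit,
        int(sel["adjusted_months"]),
        "imputed",
        donor_rid=sel["rid"],
        donor_visit=int(sel["viscode_months"]),
        replicate_id=replicate_id,
    )


def _prepare(cohort: pd.DataFrame, config: MatchConfig):
    """Classify subjects, adjust converters, build the donor pool and freeze
    the normalization ranges.  Shared by the original run and replicates."""
    converters: list[pd.DataFrame] = []
    statics: list[tuple[pd.DataFrame, str]] = []
    excluded: list[dict] = []
    for rid, tl in cohort.groupby("rid", sort=True):
        try:
            cls = classify_subject(tl)
        except AnomalousTimelineError as exc:
            logger.warning("subject %s excluded: %s", rid, exc)
            excluded.append({"rid": rid, "reason": str(exc)})
            continue
        if cls == "converter":
            converters.append(tl)
        else:
            statics.append((tl, cls))

    conv_maps = (
        pd.concat([adjust_converter(tl) for tl in converters], ignore_index=True)
        if converters
        else pd.DataFrame(columns=MAP_COLUMNS)
    )
    pool = pd.DataFrame(columns=["rid", "viscode_months", "adjusted_months"])
    if converters:
        conv_visits = pd.concat(converters, ignore_index=True)
        pool = conv_visits.merge(
            conv_maps[["rid", "viscode_months", "adjusted_months"]],
            on=["rid", "viscode_months"],
        )
        pool = pool.dropna(subset=list(config.match_vars)).reset_index(drop=True)

    if config.ranges is not None:
        ranges = dict(config.ranges)
    else:
        if pool.empty:
            raise ImputationError("cannot derive ranges: empty donor pool")
        ranges = {}
        for var in config.match_vars:
            width = float(pool[var].max() - pool[var].min())
            if width <= 0:
                raise ImputationError(f"degenerate range for {var}")
            ranges[var] = width
    return conv_maps, statics, pool, ranges, excluded


def build_adjusted_times(
    cohort: pd.DataFrame, config: MatchConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Build the original (replicate 0) visit -> adjusted-month map.

    Converters anchor on their own conversion visit; static subjects are
    imputed with ``rank_policy="best"``.  Returns the map plus metadata
    (frozen normalization ranges, excluded subjects).
    """
    config = config or MatchConfig()
    conv_maps, statics, pool, ranges, excluded = _prepare(cohort, config)
    parts = [conv_maps]
    for tl, cls in statics:
        parts.append(
            impute_static_anchor(
                tl, pool, ranges, rank_policy="best", subject_class=cls
            )
        )
    out = pd.concat(parts, ignore_index=True).sort_values(
        ["rid", "viscode_months"], kind="mergesort"
    ).reset_index(drop=True)
    meta = {"ranges": ranges, "excluded": excluded}
    return out, meta


def build_replicates(
    cohort: pd.DataFrame, config: MatchConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Original map plus ``n_replicates`` top-k random re-imputations.

    Replicate ``r`` (1-based) draws each static subject's donor uniformly
    from its k closest matches using seed ``config.seed + r``; converters
    are identical across replicates.  Distances are computed once per
    subject, so 1000 replicates cost little more than one.
    """
    config = config or MatchConfig()
    conv_maps, statics, pool, ranges, excluded = _prepare(cohort, config)

    # Pre-rank donors once per static subject.
    ranked_per_static = []
    for tl, cls in statics:
        tl_sorted = tl.sort_values("viscode_months")
        query = tl_sorted.iloc[-1] if cls == "static_MCI" else tl_sorted.iloc[0]
        if any(pd.isna(query.get(v)) for v in ranges):
            raise ImputationError(
                f"subject {query['rid']}: matching covariates missing at the "
                "comparison visit"
            )
        ranked = _donor_distances(query, pool, ranges)
        ranked_per_static.append((tl_sorted, int(query["viscode_months"]), ranked))

    parts = []
    # replicate 0: best match
    for tl_sorted, anchor_visit, ranked in ranked_per_static:
        sel = ranked.iloc[0]
        parts.append(
            _rigid_rows(tl_sorted, anchor_visit, int(sel["adjusted_months"]),
                        "imputed", sel["rid"], int(sel["viscode_months"]), 0)
        )
    original = pd.concat([conv_maps] + parts, ignore_index=True) if parts else conv_maps
    all_parts = [original]

    n_conv = len(conv_maps)
    for r in range(1, config.n_replicates + 1):
        rng = np.random.default_rng(config.seed + r)
        rep_parts = []
        if n_conv:
            cm = conv_maps.copy()
            cm["replicate_id"] = r
            rep_parts.append(cm)
        for tl_sorted, anchor_visit, ranked in ranked_per_static:
            j = int(rng.integers(0, min(config.k, len(ranked))))
            sel = ranked.iloc[j]
            rep_parts.append(
                _rigid_rows(tl_sorted, anchor_visit, int(sel["adjusted_months"]),
                            "imputed", sel["rid"], int(sel["viscode_months"]), r)
            )
        all_parts.append(pd.concat(rep_parts, ignore_index=True))

    out = pd.concat(all_parts, ignore_index=True)
    out = out.sort_values(
        ["replicate_id", "rid", "viscode_months"], kind="mergesort"
    ).reset_index(drop=True)
    return out, {"ranges": ranges, "excluded": excluded}


# ---------------------------------------------------------------------------
# KS validation


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov--Smirnov statistic (max ECDF distance)."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def _boot_p(
    x: np.ndarray, y: np.ndarray, observed: float, n_boot: int, rng: np.random.Generator
) -> float:
    """Bootstrap p-value: resample both samples with replacement from the
    pooled values; p = proportion of bootstrap statistics >= observed."""
    pooled = np.concatenate([x, y])
    n, m, total = len(x), len(y), len(x) + len(y)
    count = 0
    for _ in range(n_boot):
        xb = pooled[rng.integers(0, total, n)]
        yb = pooled[rng.integers(0, total, m)]
        if ks_statistic(xb, yb) >= observed - 1e-12:
            count += 1
    return count / n_boot


def ks_validate(
    original_times: np.ndarray,
    replicate_times: Mapping[int, np.ndarray] | pd.DataFrame,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrapped two-sample KS test of each replicate against the original.

    ``replicate_times`` is either a mapping replicate_id -> adjusted-time
    sample or a replicate map DataFrame (replicate 0 is then treated as the
    original and skipped).  Returns one row per replicate with the KS
    statistic, bootstrap p-value and rejection flag at level ``alpha``.
    """
    if isinstance(replicate_times, pd.DataFrame):
        groups = {
            int(r): g["adjusted_months"].to_numpy(float)
            for r, g in replicate_times.groupby("replicate_id")
            if int(r) != 0
        }
    else:
        groups = {int(r): np.asarray(v, float) for r, v in replicate_times.items()}
    x = np.asarray(original_times, dtype=float)
    rows = []
    for r in sorted(groups):
        rng = np.random.default_rng(seed + r)
        y = groups[r]
        stat = ks_statistic(x, y)
        p = _boot_p(x, y, stat, n_boot, rng)
        rows.append(
            {"replicate_id": r, "statistic": stat, "p_value": p, "reject": p < alpha}
        )
    return pd.DataFrame(rows, columns=["replicate_id", "statistic", "p_value", "reject"])


def ks_summary(results: pd.DataFrame) -> dict:
    """Min / mean / standard deviation of the replicate p-values (the
    per-variable summary the validation reports)."""
    p = results["p_value"].to_numpy(float)
    return {
        "min": float(p.min()),
        "mean": float(p.mean()),
        "sd": float(p.std(ddof=1)) if len(p) > 1 else 0.0,
        "n_reject": int(results["reject"].sum()),
        "n": int(len(p)),
    }
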