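"""Reading, writing and merging of the pipeline's on-disk formats.

Volumes are NIfTI-1 integer label maps (one label per anatomical region,
0 = background).  Tabular inputs are plain CSV: longitudinal visit tables
keyed by subject ID (``rid``) and months since baseline (``viscode_months``),
and a contralateral region-pair table (``pair_id,name,left_label,right_label``).
This module also applies the cohort inclusion filter: subjects who stay
cognitively normal (NL) at every visit, or who never carry a required
covariate, are excluded before any longitudinal analysis.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "FormatError",
    "OrientationError",
    "DuplicateKeyError",
    "read_label_volume",
    "write_label_volume",
    "read_region_pairs",
    "default_pair_table",
    "normalize_viscode",
    "merge_visit_tables",
    "filter_cohort",
]

DIAGNOSES = ("NL", "MCI", "AD")

#: Matching covariates / core clinical columns a visit table may carry.
VISIT_VALUE_COLUMNS = (
    "diagnosis", "mmse", "adni_mem", "age", "csf_abeta", "csf_tau", "csf_ptau",
)


class FormatError(ValueError):
    """Input file violates the expected format (e.g. float-valued label map)."""


class OrientationError(ValueError):
    """Volume orientation cannot be determined and no override was given."""


class DuplicateKeyError(ValueError):
    """A source table repeats a (rid, viscode) key."""


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer label map with physical metadata.

    Attributes
    ----------
    voxels : ndarray of int, 3D
        Region labels; 0 is background.
    spacing : tuple of float
        Per-axis voxel size in mm, in array-axis order.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0).
    lr_axis : int
        Array axis running left--right, derived from the NIfTI orientation
        (the axis whose axcode is L or R).  The hemispheric reflection step
        flips along this axis.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    lr_axis: int

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(f"label volume must be 3D, got {vox.ndim}D")
        if not np.issubdtype(vox.dtype, np.integer):
            raise FormatError(f"label volume must be integer-valued, got {vox.dtype}")
        if vox.size and vox.min() < 0:
            raise FormatError("labels must be non-negative")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.lr_axis not in (0, 1, 2):
            raise OrientationError(f"lr_axis must be 0, 1 or 2, got {self.lr_axis}")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.voxels)
        return u[u != 0]


def read_label_volume(path, lr_axis: int | None = None) -> LabelVolume:
    """Read a NIfTI label map, inferring the left--right axis from orientation.

    Parameters
    ----------
    path : str or Path
        NIfTI file with integer voxel values.
    lr_axis : int, optional
        Override for the left--right axis when orientation metadata is
        absent or untrusted.  Without an override, an unusable affine is an
        error rather than a guess.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(
            f"{path}: label volumes must hold integers, got dtype {data.dtype}"
        )
    affine = img.affine
    if lr_axis is None:
        # NIfTI marks orientation validity via the sform/qform codes; with
        # both unset nibabel synthesizes a guess, which we refuse to trust.
        hdr = img.header
        codes_unset = (
            "sform_code" in hdr
            and "qform_code" in hdr
            and int(hdr["sform_code"]) == 0
            and int(hdr["qform_code"]) == 0
        )
        if (
            affine is None
            or codes_unset
            or not np.all(np.isfinite(affine))
            or abs(np.linalg.det(affine[:3, :3])) < 1e-12
        ):
            raise OrientationError(
                f"{path}: orientation metadata unusable; pass lr_axis explicitly"
            )
        axcodes = nib.aff2axcodes(affine)
        candidates = [i for i, c in enumerate(axcodes) if c in ("L", "R")]
        if not candidates:
            raise OrientationError(
                f"{path}: no axis maps to left-right (axcodes {axcodes})"
            )
        lr_axis = candidates[0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = (
        tuple(float(v) for v in affine[:3, 3]) if affine is not None else (0.0, 0.0, 0.0)
    )
    return LabelVolume(np.asarray(data), spacing, origin, int(lr_axis))


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a :class:`LabelVolume` as NIfTI-1, encoding ``lr_axis`` in the affine.

    The affine maps the left--right array axis to the physical R axis and the
    remaining axes, in order, to A and S; a read-back therefore recovers the
    voxel array, spacing, origin and ``lr_axis`` exactly.
    """
    phys = {vol.lr_axis: 0}
    nxt = 1
    for ax in range(3):
        if ax not in phys:
            phys[ax] = nxt
            nxt += 1
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for ax in range(3):
        affine[phys[ax], ax] = vol.spacing[ax]
    affine[:3, 3] = vol.origin
    data = np.asarray(vol.voxels)
    if data.dtype.itemsize > 4:
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# region-pair tables

_PAIR_COLUMNS = ["pair_id", "name", "left_label", "right_label"]


def read_region_pairs(path, expect_rows: int | None = None) -> pd.DataFrame:
    """Read and validate a contralateral region-pair CSV.

    Each row names one left/right pair of region labels.  Labels must be
    distinct within a row and unique across the table (each region belongs
    to exactly one pair).
    """
    pairs = pd.read_csv(path)
    missing = [c for c in _PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise FormatError(f"pair table missing columns {missing}")
    pairs = pairs[_PAIR_COLUMNS].copy()
    if (pairs["left_label"] == pairs["right_label"]).any():
        raise FormatError("pair table has a row with left_label == right_label")
    all_labels = pd.concat([pairs["left_label"], pairs["right_label"]])
    if all_labels.duplicated().any():
        dup = sorted(all_labels[all_labels.duplicated()].unique())
        raise FormatError(f"labels appear in more than one pair row: {dup}")
    if expect_rows is not None and len(pairs) != expect_rows:
        raise FormatError(f"expected {expect_rows} pair rows, got {len(pairs)}")
    return pairs


def default_pair_table() -> pd.DataFrame:
    """The packaged 40-pair table for the 83-region (Hammers-style) labeling.

    Label IDs follow the published n30r83 numbering convention; site-specific
    label maps may differ, in which case the user supplies their own CSV.
    """
    with resources.files("asymtraj.data").joinpath("pairs_83region.csv").open("rb") as fh:
        return read_region_pairs(fh, expect_rows=40)


# ---------------------------------------------------------------------------
# visit tables

_VISCODE_RE = re.compile(r"^m(\d+)$")


def normalize_viscode(code) -> int:
    """Normalize an ADNI-style visit code to integer months since baseline.

    Accepts integers, numeric strings, ``"bl"``/``"sc"`` (baseline/screening
    -> 0) and ``"m06"``-style month codes.
    """
    if isinstance(code, (int, np.integer)):
        if code < 0:
            raise FormatError(f"negative visit month {code}")
        return int(code)
    if isinstance(code, float) and float(code).is_integer():
        return normalize_viscode(int(code))
    if isinstance(code, str):
        s = code.strip().lower()
        if s in ("bl", "sc"):
            return 0
        m = _VISCODE_RE.match(s)
        if m:
            return int(m.group(1))
        if s.isdigit():
            return int(s)
    raise FormatError(f"unrecognized visit code {code!r}")


def _normalize_keys(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    if "rid" not in t.columns:
        raise FormatError("visit table lacks an 'rid' column")
    if "viscode_months" in t.columns:
        t["viscode_months"] = t["viscode_months"].map(normalize_viscode)
    elif "viscode" in t.columns:
        t["viscode_months"] = t["viscode"].map(normalize_viscode)
        t = t.drop(columns=["viscode"])
    else:
        raise FormatError("visit table lacks a 'viscode_months' (or 'viscode') column")
    return t


def merge_visit_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Outer-merge per-variable visit tables onto the diagnosis table.

    The first table defines the cohort: one output row per (rid,
    viscode_months) it contains.  Columns from the remaining tables are
    joined where keys match and left missing otherwise; a column present in
    several tables is filled from the leftmost table that has a value.
    Duplicate keys within any single source table raise
    :class:`DuplicateKeyError` listing the offenders.
    """
    if not tables:
        raise ValueError("no tables to merge")
    keys = ["rid", "viscode_months"]
    merged: pd.DataFrame | None = None
    for i, raw in enumerate(tables):
        t = _normalize_keys(raw)
        dup = t.duplicated(subset=keys, keep=False)
        if dup.any():
            offenders = [
                (int(r), int(v))
                for r, v in t.loc[dup, keys].drop_duplicates().itertuples(index=False)
            ]
            raise DuplicateKeyError(f"table {i} repeats keys: {offenders}")
        if merged is None:
            merged = t
            continue
        overlap = [c for c in t.columns if c in merged.columns and c not in keys]
        out = merged.merge(t, on=keys, how="left", suffixes=("", "__rhs"))
        for c in overlap:
            out[c] = out[c].combine_first(out[c + "__rhs"])
            out = out.drop(columns=[c + "__rhs"])
        merged = out
    return merged.sort_values(keys).reset_index(drop=True)


def filter_cohort(
    visits: pd.DataFrame, required_fields: Sequence[str] = ("mmse", "adni_mem", "age")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion criteria.

    Removes subjects whose diagnosis is NL at every visit (no disease signal
    to align to), and subjects for whom a required field is missing at every
    visit.  Returns the surviving rows and a per-subject exclusion log with
    columns ``rid`` and ``reason``.
    """
    if "diagnosis" not in visits.columns:
        raise FormatError("visit table lacks a 'diagnosis' column")
    log_rows = []
    excluded: set = set()
    for rid, grp in visits.groupby("rid", sort=True):
        if (grp["diagnosis"] == "NL").all():
            log_rows.append({"rid": rid, "reason": "always_NL"})
            excluded.add(rid)
            continue
        for field in required_fields:
            present = field in grp.columns and grp[field].notna().any()
            if not present:
                log_rows.append({"rid": rid, "reason": f"missing_{field}"})
                excluded.add(rid)
    kept = visits[~visits["rid"].isin(excluded)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["rid", "reason"])
    if kept.empty:
        warnings.warn("cohort filter removed every subject", stacklevel=2)
    return kept, log
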