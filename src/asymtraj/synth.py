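"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators, each emitting its ground truth alongside the data:

* :func:`make_paired_volume` -- a labeled 3D volume holding one contralateral
  pair of ellipsoidal regions with controllable size ratio, smooth boundary
  asymmetry and a known rigid offset of the left region.  Stands in for a
  MAPER-style segmentation of a structural MRI.
* :func:`simulate_cohort` -- a longitudinal visit table mixing MCI-to-AD
  converters with static subjects, where every biomarker follows a staggered
  sigmoid time course on the conversion-anchored ("adjusted") time scale.

Each trajectory is the observable subsection of a sigmoid course: its slope
transitions logistically from a pre-inflection to a post-inflection rate,

    value(t) = v0 + p1 * (t - psi)
                  + (p2 - p1) * tau * [softplus((t - psi) / tau) - ln 2],

with softplus(x) = ln(1 + e^x).  Far from the inflection the curve is
linear with slope p1 (before) or p2 (after); the transition has logistic
shape with time scale ``tau``.  The two asymptotic lines intersect exactly
at ``psi``, so the "true knot" of the two-segment linear approximation is
``knot_months`` itself, with no offset.  (A full generalized-logistic value
curve bends twice -- takeoff and landing; within a follow-up window that
covers the MCI-to-AD transition only one of those bends is observed, which
is precisely what a single-knot spline can describe.  The generator
therefore realizes that observable subsection directly and leaves the far
side of each sigmoid outside the window.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import LabelVolume

__all__ = [
    "GenerationError",
    "ShapeSpec",
    "PairedVolume",
    "make_paired_volume",
    "TrajectorySpec",
    "trajectory_value",
    "default_trajectories",
    "SimulatedCohort",
    "simulate_cohort",
    "DEFAULT_VISIT_GRID",
]

DEFAULT_VISIT_GRID = (0, 6, 12, 18, 24, 36, 48)


class GenerationError(ValueError):
    """Requested geometry cannot be generated without bias (e.g. clipping)."""


# ---------------------------------------------------------------------------
# paired 3D regions


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of one synthetic contralateral region pair.

    The right region is an axis-aligned ellipsoid.  The left region is its
    mirror image, scaled to volume ratio ``1/size_ratio``, radially deformed
    by a low-order spherical-harmonic modulation of amplitude
    ``shape_perturbation`` (left side only), then rotated and translated by
    the recorded ground-truth rigid transform.
    """

    base_radii: tuple[float, float, float] = (12.0, 9.0, 7.0)
    size_ratio: float = 1.0
    shape_perturbation: float = 0.0
    true_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # axis-angle, rad
    true_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.base_radii):
            raise GenerationError("base_radii must be positive")
        if self.size_ratio <= 0:
            raise GenerationError("size_ratio must be positive")
        if self.shape_perturbation < 0:
            raise GenerationError("shape_perturbation must be >= 0")


@dataclass(frozen=True)
class PairedVolume:
    """A generated label volume plus its answer key (and optional intensity)."""

    volume: LabelVolume
    truth: dict
    intensity: np.ndarray | None = None


def _l2_modulation(unit_dirs: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Real degree-2 spherical-harmonic radial modulation, evaluated on unit
    direction vectors of shape (..., 3).  Smooth and low-frequency, so the
    deformed boundary stays star-shaped for moderate amplitudes."""
    x, y, z = unit_dirs[..., 0], unit_dirs[..., 1], unit_dirs[..., 2]
    y20 = 0.5 * (3.0 * z * z - 1.0)
    y21 = x * z
    y22 = x * x - y * y
    return coeffs[0] * y20 + coeffs[1] * y21 + coeffs[2] * y22


def _modulated_ellipsoid(
    rel: np.ndarray,
    radii: np.ndarray,
    amp: float,
    coeffs: np.ndarray | None,
) -> np.ndarray:
    """Membership of points ``rel`` (coords relative to center, shape (...,3))
    in an ellipsoid with radial modulation ``1 + amp*Y(direction)``."""
    v = rel / radii
    rho = np.linalg.norm(v, axis=-1)
    if amp == 0.0 or coeffs is None:
        return rho <= 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(rho[..., None] > 0, v / np.maximum(rho, 1e-30)[..., None], 0.0)
    f = 1.0 + amp * _l2_modulation(dirs, coeffs)
    return rho <= f


def make_paired_volume(
    spec: ShapeSpec,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    left_label: int = 2,
    right_label: int = 1,
    lr_axis: int = 0,
    with_intensity: bool = False,
) -> PairedVolume:
    """Generate a label volume holding one contralateral region pair.

    The two regions sit symmetrically about the mid-plane of ``lr_axis``;
    with ``size_ratio == 1``, zero perturbation and an identity transform the
    left mask is the exact voxel-wise mirror image of the right mask.

    Raises
    ------
    GenerationError
        If either region touches the grid boundary (which would bias the
        exposed-face surface-area estimate) or the regions overlap.
    """
    rng = np.random.default_rng(spec.seed)
    coeffs = rng.normal(size=3)
    coeffs /= np.linalg.norm(coeffs)

    dims = np.asarray(shape, dtype=float)
    mid = (dims - 1.0) / 2.0
    offset = dims[lr_axis] / 4.0
    c_right = mid.copy()
    c_right[lr_axis] += offset
    c_left = mid.copy()
    c_left[lr_axis] -= offset

    idx = np.indices(shape, dtype=float)  # (3, nx, ny, nz)
    coords = np.moveaxis(idx, 0, -1)  # (..., 3)

    radii = np.asarray(spec.base_radii, dtype=float)
    right_mask = _modulated_ellipsoid(coords - c_right, radii, 0.0, None)

    # Left region: undo translation and rotation, mirror into the right-shape
    # frame, then test the scaled/modulated ellipsoid.
    scale = spec.size_ratio ** (-1.0 / 3.0)
    rot = Rotation.from_rotvec(np.asarray(spec.true_rotation, dtype=float))
    rel = coords - (c_left + np.asarray(spec.true_translation, dtype=float))
    flat = rel.reshape(-1, 3)
    if np.any(np.asarray(spec.true_rotation) != 0):
        flat = rot.inv().apply(flat)
    flat = flat.copy()
    flat[:, lr_axis] *= -1.0  # mirror
    left_mask = _modulated_ellipsoid(
        flat.reshape(rel.shape), radii * scale, spec.shape_perturbation, coeffs
    )

    if np.any(right_mask & left_mask):
        raise GenerationError("regions overlap; enlarge the grid or shrink radii")
    for mask, side in ((right_mask, "right"), (left_mask, "left")):
        if not mask.any():
            raise GenerationError(f"{side} region is empty on this grid")
        for ax in range(3):
            edge = [slice(None)] * 3
            for i in (0, -1):
                edge[ax] = i
                if mask[tuple(edge)].any():
                    raise GenerationError(
                        f"{side} region touches the grid boundary on axis {ax}"
                    )

    voxels = np.zeros(shape, dtype=np.int16)
    voxels[right_mask] = right_label
    voxels[left_mask] = left_label
    volume = LabelVolume(voxels, tuple(spacing), (0.0, 0.0, 0.0), lr_axis)

    intensity = None
    if with_intensity:
        intensity = np.zeros(shape, dtype=float)
        intensity[right_mask | left_mask] = 100.0
        if spec.noise_sigma > 0:
            intensity += rng.normal(0.0, spec.noise_sigma, size=shape)

    truth = {
        "right_label": right_label,
        "left_label": left_label,
        "right_voxels": int(right_mask.sum()),
        "left_voxels": int(left_mask.sum()),
        "center_right": tuple(c_right),
        "center_left": tuple(c_left),
        "size_ratio": spec.size_ratio,
        "scale_left": scale,
        "shape_perturbation": spec.shape_perturbation,
        "true_rotation": tuple(spec.true_rotation),
        "true_translation": tuple(spec.true_translation),
        "modulation_coeffs": tuple(coeffs),
        "lr_axis": lr_axis,
        "seed": spec.seed,
    }
    return PairedVolume(volume, truth, intensity)


# ---------------------------------------------------------------------------
# longitudinal cohorts


@dataclass(frozen=True)
class TrajectorySpec:
    """Sigmoid time course of one biomarker on the adjusted-time scale.

    ``knot_months`` is the true breakpoint of the two-segment linear
    approximation (conversion event = 0): the asymptotic slope is
    ``pre_slope`` before it and ``post_slope`` after it (units/month), with
    a logistic slope transition of time scale ``tau`` between the regimes.
    ``baseline_value`` anchors the curve: value(knot_months) == baseline_value.
    """

    name: str
    knot_months: float
    pre_slope: float
    post_slope: float
    baseline_value: float
    noise_sd: float = 0.0
    direction: str | None = None  # "increasing" | "decreasing"; inferred if None
    tau: float = 8.0  # logistic time scale, months
    clip: tuple[float, float] | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.direction is not None:
            dominant = (
                self.post_slope
                if abs(self.post_slope) >= abs(self.pre_slope)
                else self.pre_slope
            )
            inferred = "increasing" if dominant > 0 else "decreasing"
            if self.direction != inferred:
                raise ValueError(
                    f"{self.name}: direction {self.direction!r} conflicts with "
                    f"slopes ({self.pre_slope}, {self.post_slope})"
                )

    @property
    def stabilizing(self) -> bool:
        """True when the curve flattens after the knot (|post| < |pre|)."""
        return abs(self.post_slope) < abs(self.pre_slope)


def trajectory_value(spec: TrajectorySpec, t) -> np.ndarray:
    """Noiseless trajectory value(s) at adjusted time ``t`` (months).

    Instantaneous slope is the logistic blend
    ``p1 + (p2 - p1) * sigmoid((t - psi) / tau)``; integrating gives the
    softplus form, anchored so that value(psi) == baseline_value.
    """
    t = np.asarray(t, dtype=float)
    x = (t - spec.knot_months) / spec.tau
    soft = np.logaddexp(0.0, x)  # ln(1 + e^x), overflow-safe
    return (
        spec.baseline_value
        + spec.pre_slope * (t - spec.knot_months)
        + (spec.post_slope - spec.pre_slope) * spec.tau * (soft - np.log(2.0))
    )


def default_trajectories() -> list[TrajectorySpec]:
    """The default biomarker panel: staggered knots in the canonical cascade
    order (CSF amyloid earliest, cognition latest), on Table-1-like scales.

    The 25-month stagger and the noise levels are set so that each knot is
    estimable with a standard error well below the spacing at a few hundred
    observations -- the regime in which validating the recovered temporal
    ordering is meaningful.  Noise here is residual scatter around the
    population trajectory; real cohorts add between-subject heterogeneity
    on top (see the methods note).
    """
    return [
        TrajectorySpec(
            "csf_abeta", knot_months=-65.0, pre_slope=-2.0, post_slope=-0.25,
            baseline_value=800.0, noise_sd=8.0, direction="decreasing", tau=10.0,
        ),
        TrajectorySpec(
            "csf_ptau", knot_months=-50.0, pre_slope=0.02, post_slope=0.18,
            baseline_value=30.0, noise_sd=2.5, direction="increasing", tau=10.0,
        ),
        TrajectorySpec(
            "csf_tau", knot_months=-35.0, pre_slope=0.15, post_slope=1.5,
            baseline_value=300.0, noise_sd=5.0, direction="increasing", tau=10.0,
        ),
        TrajectorySpec(
            "adni_mem", knot_months=-15.0, pre_slope=-0.008, post_slope=-0.035,
            baseline_value=0.0, noise_sd=0.12, direction="decreasing", tau=10.0,
        ),
        TrajectorySpec(
            "mmse", knot_months=10.0, pre_slope=-0.05, post_slope=-0.28,
            baseline_value=24.0, noise_sd=0.9, direction="decreasing", tau=10.0,
            clip=(0.0, 30.0), integer=True,
        ),
    ]


@dataclass(frozen=True)
class SimulatedCohort:
    """Visit table plus its answer key."""

    visits: pd.DataFrame
    subjects: pd.DataFrame  # rid, class, conversion_offset_months
    biomarkers: pd.DataFrame  # name, knot_months, slopes, tau, direction
    specs: list[TrajectorySpec] = field(repr=False, default_factory=list)


def simulate_cohort(
    n_subjects: int = 150,
    visit_grid_months: Sequence[int] = DEFAULT_VISIT_GRID,
    specs: Sequence[TrajectorySpec] | None = None,
    converter_fraction: float = 0.28,
    static_mix: tuple[float, float, float] = (0.25, 0.45, 0.30),
    seed: int = 0,
    covariate_noise_sd: float = 0.0,
) -> SimulatedCohort:
    """Simulate a longitudinal cohort of converters and static subjects.

    Every subject carries a latent conversion offset: the month (on the
    observed visit scale) at which their MCI-to-AD conversion occurs or
    would occur.  Converters convert at an observed visit; static-MCI and
    static-NL subjects would convert after their last visit, static-AD
    subjects converted before baseline.  Biomarker values are the sigmoid
    trajectories evaluated at ``viscode - offset`` plus Gaussian noise.

    Parameters
    ----------
    converter_fraction : float
        Probability a subject converts within the observation window.
    static_mix : tuple
        Relative weights of (NL, MCI, AD) among static subjects.
    covariate_noise_sd : float
        Extra noise added to the matching covariates (mmse, adni_mem, age)
        on top of their trajectory noise; 0 leaves them as generated.
    """
    grid = [int(v) for v in visit_grid_months]
    if grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("visit grid must be strictly increasing from 0")
    if not 0.0 <= converter_fraction <= 1.0:
        raise ValueError("converter_fraction must be in [0, 1]")
    mix = np.asarray(static_mix, dtype=float)
    if mix.min() < 0 or mix.sum() <= 0:
        raise ValueError("static_mix must be non-negative with positive sum")
    mix = mix / mix.sum()
    if specs is None:
        specs = default_trajectories()

    rng = np.random.default_rng(seed)
    last = grid[-1]
    visit_rows = []
    subject_rows = []
    for rid in range(1, n_subjects + 1):
        if rng.random() < converter_fraction:
            cls = "converter"
            offset = int(rng.choice(grid[1:]))
        else:
            cls = str(rng.choice(["static_NL", "static_MCI", "static_AD"], p=mix))
            if cls == "static_AD":
                offset = -int(rng.integers(0, 37))
            elif cls == "static_MCI":
                offset = last + int(rng.integers(6, 49))
            else:  # static_NL: conversion far beyond the window
                offset = last + int(rng.integers(48, 97))
        age0 = float(np.clip(rng.normal(73.8, 5.5), 54.0, 91.0))
        subject_rows.append(
            {"rid": rid, "class": cls, "conversion_offset_months": offset}
        )
        for v in grid:
            adj = v - offset
            if cls == "converter":
                diagnosis = "AD" if v >= offset else "MCI"
            else:
                diagnosis = {"static_NL": "NL", "static_MCI": "MCI", "static_AD": "AD"}[cls]
            row = {
                "rid": rid,
                "viscode_months": v,
                "diagnosis": diagnosis,
                "age": age0 + v / 12.0,
            }
            for spec in specs:
                val = float(trajectory_value(spec, adj))
                if spec.noise_sd > 0:
                    val += float(rng.normal(0.0, spec.noise_sd))
                if spec.name in ("mmse", "adni_mem") and covariate_noise_sd > 0:
                    val += float(rng.normal(0.0, covariate_noise_sd))
                if spec.clip is not None:
                    val = float(np.clip(val, *spec.clip))
                if spec.integer:
                    val = float(int(round(val)))
                row[spec.name] = val
            if covariate_noise_sd > 0:
                row["age"] += float(rng.normal(0.0, covariate_noise_sd))
            visit_rows.append(row)

    visits = pd.DataFrame(visit_rows)
    subjects = pd.DataFrame(subject_rows)
    biomarkers = pd.DataFrame(
        [
            {
                "name": s.name,
                "knot_months": s.knot_months,
                "pre_slope": s.pre_slope,
                "post_slope": s.post_slope,
                "tau": s.tau,
                "direction": s.direction
                or ("increasing" if (s.post_slope if not s.stabilizing else s.pre_slope) > 0 else "decreasing"),
            }
            for s in specs
        ]
    )
    return SimulatedCohort(visits, subjects, biomarkers, list(specs))
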