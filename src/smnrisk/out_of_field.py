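"""Out-of-field dose estimation for photon CSI.

Planning systems are accurate in-field but unreliable outside the treatment
field.  Three estimation approaches are implemented:

1. **TPS only** — take the planning-system voxel doses as they are.
2. **Volume-weighted averaging** — for organs partially in-field, a
   sensitivity rule decides whether the planning system is adequate
   (perturb sub-5%-isodose voxels by +/-60%; trigger if the organ mean moves
   by more than 5%); organs fully out-of-field, and partial organs that
   trigger, combine the in-field planning-system dose with the mean of point
   (TLD-style) measurements, weighted by the volume fraction in-field.
3. **Model-based replacement** — every voxel outside the 50% isodose surface
   and more than 1 cm from its nearest vertex is replaced with a fitted
   two-Gaussian function of distance from the field edge.

Distance to the field edge is the Euclidean distance to the nearest sampled
vertex of the isodose surface (not point-to-triangle), so the surface vertex
sampling density bounds the distance error.  "Inside" a given isodose surface
is decided by the voxel dose exceeding the level threshold, standing in for
the planning system's closed contoured structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import OUT_OF_FIELD_PARAMS
from .grids import DensityGrid, DoseGrid, mean_organ_equivalent_dose

__all__ = [
    "IsodoseSurface",
    "OutOfFieldModelParams",
    "PointMeasurement",
    "FieldPosition",
    "distance_to_surface",
    "distances_to_surface",
    "out_of_field_model_dose",
    "replace_out_of_field",
    "sensitivity_analysis",
    "volume_weighted_organ_dose",
    "classify_field_position",
]

MM_PER_CM = 10.0
#: Guard band outside the 50% surface inside which TPS values are kept (cm).
GUARD_BAND_CM = 1.0


@dataclass(frozen=True)
class IsodoseSurface:
    """An isodose surface sampled as a vertex cloud in patient space (mm)."""

    level: float  # fraction of prescription, e.g. 0.50 or 0.05
    vertices: np.ndarray  # (n, 3) points, mm

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "vertices", v)
        if not 0 < self.level < 1:
            raise ValueError("isodose level must lie in (0, 1)")
        if v.size == 0 or v.shape[1] != 3:
            raise ValueError("surface needs a non-empty (n, 3) vertex list")


@dataclass(frozen=True)
class OutOfFieldModelParams:
    """Fitted two-Gaussian peripheral-dose model parameters.

    Absorbed dose per unit prescribed dose, in cGy/Gy, as a function of
    distance r (cm) from the field edge; alphas in cm*cGy/Gy, mus/sigmas in
    cm.  The negative fitted means place the Gaussian peaks inside the field,
    so the model decreases monotonically over the out-of-field region.
    """

    alpha1: float = OUT_OF_FIELD_PARAMS["alpha1"]
    mu1: float = OUT_OF_FIELD_PARAMS["mu1"]
    sigma1: float = OUT_OF_FIELD_PARAMS["sigma1"]
    alpha2: float = OUT_OF_FIELD_PARAMS["alpha2"]
    mu2: float = OUT_OF_FIELD_PARAMS["mu2"]
    sigma2: float = OUT_OF_FIELD_PARAMS["sigma2"]

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian widths must be positive")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("Gaussian amplitudes must be non-negative")


@dataclass(frozen=True)
class PointMeasurement:
    """A point equivalent-dose measurement (TLD-style) inside an organ."""

    organ: str
    position_mm: tuple[float, float, float]
    H_Sv: float

    def __post_init__(self):
        if self.H_Sv < 0:
            raise ValueError("measured equivalent dose must be non-negative")


@dataclass(frozen=True)
class FieldPosition:
    """An organ's relation to the treatment field (5% isodose surface)."""

    organ: str
    category: str  # in-field | partially-in-field | out-of-field
    fraction_in_5pct: float

    def __post_init__(self):
        f = self.fraction_in_5pct
        if not 0 <= f <= 1:
            raise ValueError("volume fraction must lie in [0, 1]")
        expected = (
            "out-of-field" if f == 0 else "in-field" if f == 1 else "partially-in-field"
        )
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with "
                f"fraction_in_5pct={f}"
            )


def distance_to_surface(point_mm: Sequence[float], surface: IsodoseSurface) -> float:
    """Distance (cm) from a patient-space point to the nearest surface vertex."""
    p = np.asarray(point_mm, dtype=float)
    d = np.linalg.norm(surface.vertices - p, axis=1)
    return float(d.min()) / MM_PER_CM


def distances_to_surface(points_mm: np.ndarray, surface: IsodoseSurface) -> np.ndarray:
    """Vectorised nearest-vertex distances (cm) for an (n, 3) point array."""
    tree = cKDTree(surface.vertices)
    d, _ = tree.query(np.atleast_2d(points_mm), k=1)
    return d / MM_PER_CM


def out_of_field_model_dose(
    r_cm: float | np.ndarray,
    params: OutOfFieldModelParams = OutOfFieldModelParams(),
    D_Rx: float = 23.4,
    w_R: float = 1.0,
) -> float | np.ndarray:
    """Equivalent dose (Sv) at distance ``r_cm`` from the field edge.

    H = w_R * D_Rx * (1/100) * sum_i alpha_i / (sqrt(2 pi) sigma_i)
        * exp(-(r - mu_i)^2 / (2 sigma_i^2))

    The 1/100 converts the model's cGy-per-Gy output to a fraction of the
    prescription.  Strictly positive, and strictly decreasing for r >= 1 cm
    with the default fitted parameters.
    """
    r = np.asarray(r_cm, dtype=float)
    total = np.zeros_like(r)
    for a, mu, s in (
        (params.alpha1, params.mu1, params.sigma1),
        (params.alpha2, params.mu2, params.sigma2),
    ):
        total = total + a / (math.sqrt(2 * math.pi) * s) * np.exp(
            -((r - mu) ** 2) / (2 * s**2)
        )
    out = w_R * D_Rx * 0.01 * total
    return float(out) if np.isscalar(r_cm) else out


def replace_out_of_field(
    grid: DoseGrid,
    surface_50: IsodoseSurface,
    params: OutOfFieldModelParams = OutOfFieldModelParams(),
    D_Rx: float = 23.4,
    w_R: float = 1.0,
) -> DoseGrid:
    """Approach 3: swap far out-of-field voxel doses for the analytic model.

    A voxel is replaced iff it is outside the 50% isodose surface (dose below
    ``0.5 * w_R * D_Rx``) *and* more than 1 cm from the surface's nearest
    vertex.  Voxels in the 1 cm guard band, and all in-field voxels, keep
    their planning-system values bit-for-bit.
    """
    if surface_50 is None:
        raise ValueError("a 50% isodose surface is required")
    threshold = surface_50.level * w_R * D_Rx
    outside = grid.values < threshold
    values = grid.values.copy()
    if outside.any():
        pts = grid.voxel_centers()[outside]
        r = distances_to_surface(pts, surface_50)
        far = r > GUARD_BAND_CM
        model = out_of_field_model_dose(r[far], params, D_Rx=D_Rx, w_R=w_R)
        replaced = values[outside]
        replaced[far] = model
        values[outside] = replaced
    return replace(grid, values=values)


def sensitivity_analysis(
    equiv: DoseGrid,
    mask: np.ndarray,
    in_5pct: np.ndarray,
    density: DensityGrid | None = None,
    perturbation: float = 0.60,
    threshold: float = 0.05,
) -> bool:
    """Decide whether the planning system suffices for a partial organ.

    Scales the organ's voxels outside the 5% isodose surface by ``1 +/-
    perturbation`` and returns True (measurements needed) iff either scaling
    changes the mean organ dose by more than ``threshold`` in relative terms.

    ``in_5pct`` is a boolean grid of voxels inside the 5% surface.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("organ mask is empty")
    base = mean_organ_equivalent_dose(equiv, mask, density)
    if base == 0:
        return False
    perturb = mask & ~np.asarray(in_5pct, dtype=bool)
    if not perturb.any():
        return False
    for factor in (1 + perturbation, 1 - perturbation):
        values = equiv.values.copy()
        values[perturb] *= factor
        perturbed = mean_organ_equivalent_dose(replace(equiv, values=values), mask, density)
        if abs(perturbed - base) / base > threshold:
            return True
    return False


def volume_weighted_organ_dose(
    H_in_field_TPS: float,
    v_in: float,
    measurements: Sequence[PointMeasurement] | Sequence[float],
) -> float:
    """Approach 2: volume-weighted blend of TPS in-field dose and measurements.

    H_T = v_in * H_TPS + (1 - v_in) * mean(measured H); a fully out-of-field
    organ (v_in = 0) takes the plain measurement mean.
    """
    if not 0 <= v_in <= 1:
        raise ValueError("in-field volume fraction must lie in [0, 1]")
    if v_in == 1:
        return H_in_field_TPS
    values = [m.H_Sv if isinstance(m, PointMeasurement) else float(m) for m in measurements]
    if not values:
        raise ValueError(
            "point measurements are required for an organ not fully in-field"
        )
    return v_in * H_in_field_TPS + (1 - v_in) * float(np.mean(values))


def classify_field_position(
    organ: str, mask: np.ndarray, in_5pct: np.ndarray
) -> FieldPosition:
    """Classify an organ by its volume fraction inside the 5% isodose surface."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("organ mask is empty")
    frac = float((mask & np.asarray(in_5pct, dtype=bool)).sum() / mask.sum())
    category = (
        "out-of-field" if frac == 0 else "in-field" if frac == 1 else "partially-in-field"
    )
    return FieldPosition(organ=organ, category=category, fraction_in_5pct=frac)
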