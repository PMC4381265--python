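"""Voxel dose grids, organ masks, and mass-weighted organ dosimetry.

All per-voxel operations require congruent grids (identical shape, spacing
and origin): upstream planning-system and Monte Carlo output is assumed to
have been resampled onto one common grid (nearest-neighbour resampling is
provided as plumbing).  Coordinates are voxel-centre, millimetres, 0-based
indices; voxel volume is uniform per grid, so the mass weights in the organ
mean reduce to densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DoseGrid",
    "StructureSet",
    "DensityGrid",
    "TruncationInfo",
    "DVH",
    "UnitError",
    "equivalent_dose_voxelwise",
    "mean_organ_equivalent_dose",
    "apply_truncation_correction",
    "density_from_ct",
    "derive_remainder",
    "compute_dvh",
    "resample_nearest",
]

ABSORBED_UNITS = ("Gy", "Gy/sp")
EQUIVALENT_UNITS = ("Sv", "Sv/sp")
_TO_EQUIVALENT = {"Gy": "Sv", "Gy/sp": "Sv/sp"}


class UnitError(ValueError):
    """Raised when grid arithmetic mixes incompatible dose units."""


@dataclass(frozen=True)
class DoseGrid:
    """A 3-D scalar dose field on a regular grid.

    Parameters
    ----------
    values
        Per-voxel dose.  Non-negative.
    spacing
        Voxel edge lengths in mm, one per axis.
    origin
        Patient-space coordinate (mm) of the centre of voxel (0, 0, 0).
    unit
        One of ``Gy``, ``Sv`` or their per-source-particle variants
        ``Gy/sp``, ``Sv/sp``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "Gy"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if v.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={v.ndim}")
        if np.any(v < 0):
            raise ValueError("dose values must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")
        if self.unit not in ABSORBED_UNITS + EQUIVALENT_UNITS:
            raise UnitError(f"unknown dose unit {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        sx, sy, sz = self.spacing
        return (sx * sy * sz) / 1000.0

    def voxel_centers(self) -> np.ndarray:
        """Patient-space centres of every voxel, shape (*grid.shape, 3), mm."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def congruent_with(self, other: "DoseGrid | DensityGrid") -> bool:
        return (
            self.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, getattr(other, "origin", self.origin))
        )


@dataclass(frozen=True)
class DensityGrid:
    """Per-voxel mass density in g/cm^3, congruent with the dose grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "uniform"  # or "from-CT-calibration"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if v.ndim != 3:
            raise ValueError("density grid must be 3-D")
        if np.any(v < 0):
            raise ValueError("densities must be non-negative")


@dataclass
class StructureSet:
    """Named binary organ masks congruent with one grid.

    The mask ``whole body`` is required for remainder derivation; every
    specific organ mask is expected to be a subset of it.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, organ: str) -> np.ndarray:
        return self.masks[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.masks

    @property
    def organs(self) -> list[str]:
        return list(self.masks)

    def specific_organs(self) -> list[str]:
        """Organs other than the whole body and the derived remainder."""
        return [o for o in self.masks if o not in ("whole body", "remainder")]


@dataclass(frozen=True)
class TruncationInfo:
    """Image-truncation correction for organs extending beyond the CT image.

    The correction multiplies the mean organ dose by the ratio of the body
    mass captured in the image to the whole-body mass, for organs whose
    inferior extent is cut off by the image (dose below the cut is assumed
    negligible).
    """

    mass_in_image_kg: float
    total_body_mass_kg: float
    applies_to: frozenset[str]

    def __post_init__(self):
        if not 0 < self.correction_ratio <= 1:
            raise ValueError(
                "correction ratio must lie in (0, 1]; got "
                f"{self.correction_ratio!r} "
                f"({self.mass_in_image_kg} / {self.total_body_mass_kg} kg)"
            )

    @property
    def correction_ratio(self) -> float:
        return self.mass_in_image_kg / self.total_body_mass_kg

    @classmethod
    def from_ratio(cls, ratio: float, applies_to: Iterable[str]) -> "TruncationInfo":
        """Build from a bare ratio (image mass normalised to the ratio itself)."""
        return cls(
            mass_in_image_kg=float(ratio),
            total_body_mass_kg=1.0,
            applies_to=frozenset(applies_to),
        )


@dataclass(frozen=True)
class DVH:
    """Differential dose-volume histogram for one organ."""

    organ: str
    bin_edges: np.ndarray  # Sv, length n_bins + 1, strictly increasing
    differential_volume: np.ndarray  # fraction of organ volume per bin

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.differential_volume, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "differential_volume", vols)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if abs(vols.sum() - 1.0) > 1e-9:
            raise ValueError("differential volumes must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_dose(self) -> float:
        """Mean organ dose recovered from the histogram (bin-centre rule)."""
        return float(np.sum(self.bin_centers * self.differential_volume))


# ---------------------------------------------------------------------------
# operations


def equivalent_dose_voxelwise(dose: DoseGrid, w_R: float) -> DoseGrid:
    """Convert absorbed dose to equivalent dose, H_v = w_R * D_v.

    ``w_R`` is the mean radiation weighting factor of the field (1 for
    photons, ~1.1 for therapeutic protons, ~9 for secondary neutrons).  The
    unit tag flips Gy -> Sv (per-source-particle variants likewise).
    """
    if dose.unit not in ABSORBED_UNITS:
        raise UnitError(
            f"equivalent dose conversion expects an absorbed-dose grid (Gy); "
            f"got unit {dose.unit!r}"
        )
    if w_R <= 0:
        raise ValueError("radiation weighting factor must be positive")
    return replace(dose, values=w_R * dose.values, unit=_TO_EQUIVALENT[dose.unit])


def mean_organ_equivalent_dose(
    equiv: DoseGrid,
    mask: np.ndarray,
    density: DensityGrid | None = None,
) -> float:
    """Mass-weighted mean equivalent dose over an organ.

    H_T = sum_{v in T} H_v rho_v / sum_{v in T} rho_v  — the voxel volume is
    uniform across the grid and cancels.  With ``density=None`` the mean is
    unweighted (uniform density).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != equiv.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid shape {equiv.shape}"
        )
    if not mask.any():
        raise ValueError("organ mask is empty")
    h = equiv.values[mask]
    if density is None:
        return float(h.mean())
    if density.values.shape != equiv.shape:
        raise ValueError("density grid not congruent with dose grid")
    rho = density.values[mask]
    wsum = rho.sum()
    if wsum <= 0:
        raise ValueError("organ has zero total mass")
    return float(np.dot(h, rho) / wsum)


def apply_truncation_correction(
    H_T: float, info: TruncationInfo, organ: str
) -> float:
    """Scale a mean organ dose for image truncation when the organ needs it."""
    if organ in info.applies_to:
        return H_T * info.correction_ratio
    return H_T


def density_from_ct(
    ct: np.ndarray,
    calibration: Iterable[tuple[float, float]],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> DensityGrid:
    """Map CT numbers to mass density with a piecewise-linear calibration.

    ``calibration`` is a sequence of (CT number, density g/cm^3) knots, with
    non-decreasing density.  CT numbers beyond the calibrated range are
    clamped to the nearest endpoint with a warning.
    """
    knots = sorted((float(x), float(y)) for x, y in calibration)
    if len(knots) < 2:
        raise ValueError("calibration needs at least two knots")
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    if np.any(np.diff(xs) <= 0):
        raise ValueError("calibration CT numbers must be strictly increasing")
    if np.any(np.diff(ys) < 0):
        raise ValueError("calibration must be monotone non-decreasing in density")
    ct = np.asarray(ct, dtype=float)
    if ct.min() < xs[0] or ct.max() > xs[-1]:
        warnings.warn(
            "CT numbers outside the calibration domain were clamped to the "
            "nearest calibration endpoint",
            stacklevel=2,
        )
    rho = np.interp(ct, xs, ys)  # np.interp clamps outside the domain
    return DensityGrid(
        values=rho, spacing=spacing, origin=origin, provenance="from-CT-calibration"
    )


#: Packaged two-segment default calibration: air -> water -> compact bone.
DEFAULT_CT_CALIBRATION = ((-1000.0, 0.00121), (0.0, 1.0), (1300.0, 1.85))


def derive_remainder(structures: StructureSet) -> np.ndarray:
    """Whole body minus the union of all specific SMN-site organ masks."""
    if "whole body" not in structures:
        raise ValueError("structure set has no 'whole body' mask")
    body = structures["whole body"]
    union = np.zeros_like(body)
    for organ in structures.specific_organs():
        union |= structures[organ]
    return body & ~union


def compute_dvh(equiv: DoseGrid, mask: np.ndarray, n_bins: int = 1000,
                organ: str = "") -> DVH:
    """Differential DVH with equal-width bins spanning the organ dose range.

    The bin-centre mean of the returned histogram matches the direct voxel
    mean to within half a bin width.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("organ mask is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    doses = equiv.values[mask]
    lo, hi = float(doses.min()), float(doses.max())
    if hi == lo:  # uniform dose: a single degenerate-width bin around it
        hi = lo + max(abs(lo), 1.0) * 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(doses, bins=edges)
    return DVH(
        organ=organ,
        bin_edges=edges,
        differential_volume=counts / counts.sum(),
    )


def resample_nearest(
    grid: DoseGrid,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
) -> DoseGrid:
    """Nearest-neighbour resampling onto a new regular grid (plumbing).

    Target voxel centres falling outside the source grid take the nearest
    edge voxel's value.
    """
    idx = []
    for ax in range(3):
        coords = origin[ax] + spacing[ax] * np.arange(shape[ax])
        i = np.rint((coords - grid.origin[ax]) / grid.spacing[ax]).astype(int)
        idx.append(np.clip(i, 0, grid.shape[ax] - 1))
    values = grid.values[np.ix_(idx[0], idx[1], idx[2])]
    return DoseGrid(values=values, spacing=spacing, origin=origin, unit=grid.unit)
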