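"""Synthetic voxel phantom and CSI dose generator.

Builds a parametric torso+head phantom (ellipsoid/cylinder primitives, not
anatomical meshes) with the contoured volumes the pipeline expects, then
synthesises modality-specific dose component grids with the geometric and
statistical structure of a craniospinal irradiation (CSI) plan:

* an in-field plateau at the prescription (23.4 Gy-RBE by default) over a
  cranial volume plus a posterior spinal slab,
* photon out-of-field dose following the packaged two-Gaussian
  distance-from-field-edge model,
* proton primary dose confined to the target with a sharp lateral/distal
  Gaussian falloff, plus external- and internal-neutron equivalent-dose
  fields that decay slowly with distance from the field and are emitted
  per source particle (exercising the beam-normalization step),
* TLD-like point measurements inside out-of-field organs.

Noise is multiplicative lognormal (dose uncertainties are relative); a
single global seed drives every stochastic draw through named substreams, so
regenerating any component is reproducible.  The pelvic organs sit far
enough below the spinal field edge to be entirely outside the 5% isodose
surface, mirroring the clinical situation in which the uterus, ovaries and
bladder are fully out-of-field.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .constants import (
    D_RX_GY_RBE,
    TRUNCATION_ORGANS,
    TRUNCATION_RATIO,
    W_R_NEUTRON_EXTERNAL,
    W_R_NEUTRON_INTERNAL,
    W_R_PROTON,
)
from .grids import (
    DEFAULT_CT_CALIBRATION,
    DensityGrid,
    DoseGrid,
    StructureSet,
    TruncationInfo,
    density_from_ct,
    derive_remainder,
)
from .out_of_field import (
    IsodoseSurface,
    OutOfFieldModelParams,
    PointMeasurement,
    distances_to_surface,
    out_of_field_model_dose,
)

__all__ = [
    "PhantomConfig",
    "SyntheticCase",
    "generate_phantom",
    "generate_csi_dose",
    "generate_tld_measurements",
    "generate_case",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named-substream generator: one global seed, independent streams."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, plan and noise parameters of a synthetic case.

    The default grid is 64 x 64 x 160 voxels at (4, 4, 4.5) mm covering a
    256 x 256 x 720 mm volume (lateral x anteroposterior x craniocaudal,
    z increasing toward the head) — roughly the imaged extent of an
    adolescent from mid-thigh to vertex.
    """

    shape: tuple[int, int, int] = (64, 64, 160)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "photon"  # or "proton"
    D_Rx: float = D_RX_GY_RBE  # Gy-RBE
    #: Spinal field: posterior slab of this lateral half-width (mm) ...
    spinal_halfwidth_mm: float = 25.0
    #: ... spanning this craniocaudal interval (mm).
    spinal_z_mm: tuple[float, float] = (180.0, 565.0)
    #: Cranial fields cover everything above this z (mm).
    cranial_z_min_mm: float = 555.0
    #: Relative (lognormal) dose noise; 0 gives exact analytic doses.
    noise_sigma: float = 0.05
    #: Source particles the per-source-particle proton grids are scaled by.
    n_source_particles: float = 2.0e15
    #: Imaged-to-total body mass ratio driving the truncation correction.
    truncation_ratio: float = TRUNCATION_RATIO
    #: Phantom mass the geometry is designed to contain (kg, imaged part).
    target_mass_kg: float = 20.0
    #: Designed span of proton neutron-component organ mean doses (Sv).
    neutron_organ_mean_range: tuple[float, float] = (0.05, 0.55)
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("photon", "proton"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise level must be non-negative")


@dataclass
class SyntheticCase:
    """Everything one generated case carries through the pipeline."""

    config: PhantomConfig
    ct: np.ndarray
    density: DensityGrid
    structures: StructureSet
    dose: dict[str, DoseGrid] = dataclass_field(default_factory=dict)
    surfaces: dict[float, IsodoseSurface] = dataclass_field(default_factory=dict)
    measurements: list[PointMeasurement] = dataclass_field(default_factory=list)
    truncation: TruncationInfo | None = None
    bnv_mask: np.ndarray | None = None
    field_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry primitives (all coordinates in mm, patient space)


def _coords(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        config.origin[i] + config.spacing[i] * np.arange(config.shape[i])
        for i in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _zcylinder(X, Y, Z, center_xy, radius, z_range) -> np.ndarray:
    return (
        ((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2) <= radius**2
    ) & (Z >= z_range[0]) & (Z <= z_range[1])


def _elliptic_zcylinder(X, Y, Z, center_xy, semi_xy, z_range) -> np.ndarray:
    return (
        ((X - center_xy[0]) / semi_xy[0]) ** 2
        + ((Y - center_xy[1]) / semi_xy[1]) ** 2
        <= 1.0
    ) & (Z >= z_range[0]) & (Z <= z_range[1])


def _body_mask(config: PhantomConfig):
    X, Y, Z = _coords(config)
    torso = _elliptic_zcylinder(X, Y, Z, (128, 128), (115, 95), (0, 520))
    neck = _zcylinder(X, Y, Z, (128, 128), 45, (520, 560))
    head = _ellipsoid(X, Y, Z, (128, 128, 640), (75, 85, 80))
    return torso | neck | head, (X, Y, Z)


#: Organ primitives: name -> list of (center, semi-axes) ellipsoids, mm.
#: The anteroposterior axis has small y anterior; the spine sits posteriorly.
_ORGAN_ELLIPSOIDS: dict[str, list[tuple[tuple, tuple]]] = {
    "thyroid": [((128, 110, 545), (18, 12, 15))],
    "lungs": [((85, 120, 440), (38, 45, 70)), ((171, 120, 440), (38, 45, 70))],
    "breasts": [((90, 55, 430), (25, 18, 20)), ((166, 55, 430), (25, 18, 20))],
    "liver": [((100, 130, 330), (55, 45, 40))],
    "stomach": [((155, 120, 340), (30, 28, 32))],
    "colon": [((128, 120, 230), (60, 40, 35))],
    "bladder": [((128, 115, 80), (25, 25, 20))],
    "uterus": [((128, 135, 105), (18, 15, 18))],
    "ovaries": [((100, 135, 115), (10, 8, 9)), ((156, 135, 115), (10, 8, 9))],
    "rectum": [((128, 170, 85), (12, 12, 30))],
}

#: Organs carved as disjoint sets, in this priority order (skin first as the
#: body shell, red bone marrow last as the spinal column + cranial vault).
_CARVE_ORDER = (
    "skin",
    "thyroid",
    "lungs",
    "breasts",
    "liver",
    "stomach",
    "colon",
    "bladder",
    "uterus",
    "ovaries",
    "rectum",
    "red bone marrow",
)


def generate_phantom(
    config: PhantomConfig,
) -> tuple[np.ndarray, StructureSet, DensityGrid]:
    """Build the CT grid, structure set and density grid of a phantom.

    Deterministic given the config (geometry carries no randomness).  The
    specific organ masks are pairwise disjoint by construction and all lie
    inside the whole-body mask; ``remainder`` is derived by Boolean
    subtraction.
    """
    body, (X, Y, Z) = _body_mask(config)
    interior = ndimage.binary_erosion(body)

    masks: dict[str, np.ndarray] = {"whole body": body}
    assigned = np.zeros_like(body)

    spine = _zcylinder(X, Y, Z, (128, 185), 14, (40, 520))
    skull = _ellipsoid(X, Y, Z, (128, 128, 640), (75, 85, 80)) & ~_ellipsoid(
        X, Y, Z, (128, 128, 640), (63, 73, 68)
    )

    for organ in _CARVE_ORDER:
        if organ == "skin":
            raw = body & ~interior
        elif organ == "red bone marrow":
            raw = (spine | skull) & interior
        else:
            raw = np.zeros_like(body)
            for center, semi in _ORGAN_ELLIPSOIDS[organ]:
                raw |= _ellipsoid(X, Y, Z, center, semi)
            raw &= interior  # keep organs off the skin shell
        mask = raw & body & ~assigned
        if not mask.any():
            raise ValueError(f"organ {organ!r} is empty on this grid")
        if not (mask & ~body).sum() == 0:
            raise ValueError(f"organ {organ!r} escapes the whole-body mask")
        masks[organ] = mask
        assigned |= mask

    structures = StructureSet(masks=masks)
    structures.masks["remainder"] = derive_remainder(structures)

    # CT numbers: air outside the body, lung parenchyma well below water,
    # bone along the spine and cranial vault, soft tissue elsewhere.
    ct = np.full(config.shape, -1000.0)
    ct[body] = 0.0
    ct[masks["lungs"]] = -700.0
    ct[(spine | skull) & body] = 700.0

    density = density_from_ct(
        ct, DEFAULT_CT_CALIBRATION, spacing=config.spacing, origin=config.origin
    )
    return ct, structures, density


def _field_mask(config: PhantomConfig) -> np.ndarray:
    """Treatment-field region: posterior spinal slab + cranial volume.

    Photon fields are beams traversing the patient, so the spinal slab spans
    the full anteroposterior extent of the grid and the cranial fields cover
    everything above their inferior edge (thyroid included, matching a plan
    irradiating the whole craniospinal axis).  Proton fields stop distally:
    the spinal target is restricted to the posterior part of the body
    housing the spinal canal and vertebrae.
    """
    X, Y, Z = _coords(config)
    spinal = (
        (np.abs(X - 128.0) <= config.spinal_halfwidth_mm)
        & (Z >= config.spinal_z_mm[0])
        & (Z <= config.spinal_z_mm[1])
    )
    if config.modality == "proton":
        spinal &= Y >= 140.0  # distal edge anterior of the vertebral bodies
    cranial = Z >= config.cranial_z_min_mm
    return spinal | cranial


def _surface_from_mask(
    mask: np.ndarray, config: PhantomConfig, level: float
) -> IsodoseSurface:
    verts, *_ = measure.marching_cubes(
        mask.astype(float), level=0.5, spacing=config.spacing
    )
    return IsodoseSurface(level=level, vertices=verts + np.asarray(config.origin))


def _surface_from_dose(
    grid: DoseGrid, level: float, threshold: float
) -> IsodoseSurface:
    verts, *_ = measure.marching_cubes(
        grid.values, level=threshold, spacing=grid.spacing
    )
    return IsodoseSurface(level=level, vertices=verts + np.asarray(grid.origin))


def _noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Multiplicative lognormal factor; exactly 1 everywhere when sigma=0."""
    if sigma == 0:
        return np.ones(shape)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_csi_dose(case: SyntheticCase, config: PhantomConfig) -> None:
    """Attach modality-specific dose component grids and isodose surfaces.

    Photon: one primary absorbed-dose grid — prescription plateau in-field,
    two-Gaussian model of distance-to-field-edge outside — plus 50% and 5%
    isodose surfaces extracted from the field region and the composite grid.

    Proton: a planning-system primary grid (absorbed dose, prescription /
    1.1 in the target, sharp Gaussian falloff outside), a per-source-particle
    primary grid, per-source-particle external- and internal-neutron
    absorbed-dose grids whose equivalent-dose organ means span the configured
    target range, and a beam normalization volume mask.
    """
    field = _field_mask(config)
    case.field_mask = field
    surface_50 = _surface_from_mask(field, config, level=0.50)
    case.surfaces[0.50] = surface_50

    # distance (cm) from every voxel centre to the field edge (50% surface)
    centers = np.stack(_coords(config), axis=-1).reshape(-1, 3)
    r = distances_to_surface(centers, surface_50).reshape(config.shape)

    sigma = config.noise_sigma
    seed = config.seed

    if config.modality == "photon":
        params = OutOfFieldModelParams()
        dose = np.where(
            field,
            config.D_Rx,
            out_of_field_model_dose(r, params, D_Rx=config.D_Rx, w_R=1.0),
        )
        dose *= _noise(_rng(seed, "photon-primary"), config.shape, sigma)
        grid = DoseGrid(
            values=dose, spacing=config.spacing, origin=config.origin, unit="Gy"
        )
        case.dose["primary"] = grid
        case.surfaces[0.05] = _surface_from_dose(
            grid, level=0.05, threshold=0.05 * config.D_Rx
        )
        case.bnv_mask = _bnv_box(config) & field
    else:
        d_phys = config.D_Rx / W_R_PROTON  # 23.4 Gy-RBE <-> 21.3 Gy
        profile = np.where(field, d_phys, d_phys * np.exp(-((r / 0.8) ** 2)))
        tps = profile * _noise(_rng(seed, "proton-tps"), config.shape, sigma)
        case.dose["primary"] = DoseGrid(
            values=tps, spacing=config.spacing, origin=config.origin, unit="Gy"
        )
        n_sp = config.n_source_particles
        mc = profile * _noise(_rng(seed, "proton-primary-sp"), config.shape, sigma)
        case.dose["primary/sp"] = DoseGrid(
            values=mc / n_sp,
            spacing=config.spacing,
            origin=config.origin,
            unit="Gy/sp",
        )
        # Designed neutron equivalent-dose fields (Sv): slowly varying with
        # distance from the field; external neutrons dominate internal ones.
        lo, hi = config.neutron_organ_mean_range
        h_ext = lo * 2 + (hi - 0.07 - 2 * lo) * np.exp(-r / 25.0)
        h_int = lo + (0.32 - lo) * np.exp(-r / 18.0)
        for name, h, w in (
            ("external neutron", h_ext, W_R_NEUTRON_EXTERNAL),
            ("internal neutron", h_int, W_R_NEUTRON_INTERNAL),
        ):
            h = h * _noise(_rng(seed, f"proton-{name}"), config.shape, sigma)
            case.dose[f"{name}/sp"] = DoseGrid(
                values=h / (w * n_sp),
                spacing=config.spacing,
                origin=config.origin,
                unit="Gy/sp",
            )
        case.bnv_mask = _bnv_box(config) & field

    if case.bnv_mask is not None and not case.bnv_mask.any():
        raise ValueError("beam normalization volume is empty on this grid")


def _bnv_box(config: PhantomConfig) -> np.ndarray:
    """Central spinal-field box of approximately uniform primary dose."""
    X, Y, Z = _coords(config)
    return (
        (np.abs(X - 128.0) <= 12.0)
        & (np.abs(Y - 185.0) <= 16.0)
        & (Z >= 300.0)
        & (Z <= 400.0)
    )


def generate_tld_measurements(
    case: SyntheticCase,
    organ: str,
    n_points: int = 8,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> list[PointMeasurement]:
    """Sample TLD-like point doses at voxels inside an organ.

    Each measurement reads the local grid equivalent dose times a
    multiplicative lognormal factor.  Deterministic given the seed.
    """
    config = case.config
    sigma = config.noise_sigma if noise_sigma is None else noise_sigma
    rng = _rng(config.seed if seed is None else seed, f"tld-{organ}")
    mask = case.structures[organ]
    idx = np.flatnonzero(mask.ravel())
    if n_points > idx.size:
        raise ValueError(
            f"requested {n_points} points but {organ!r} has only {idx.size} voxels"
        )
    chosen = rng.choice(idx, size=n_points, replace=False)
    primary = case.dose["primary"]
    coords = np.unravel_index(chosen, config.shape)
    factors = _noise(rng, n_points, sigma)
    w_R = 1.0 if config.modality == "photon" else W_R_PROTON
    out = []
    for k in range(n_points):
        i, j, l = coords[0][k], coords[1][k], coords[2][k]
        pos = tuple(
            config.origin[a] + config.spacing[a] * (i, j, l)[a] for a in range(3)
        )
        H = w_R * primary.values[i, j, l] * factors[k]
        out.append(PointMeasurement(organ=organ, position_mm=pos, H_Sv=float(H)))
    return out


#: Organs given TLD measurements by default: the pelvic volumes that lie
#: entirely outside the treatment field in this plan geometry.
DEFAULT_TLD_ORGANS = ("bladder", "uterus", "ovaries", "rectum")


def generate_case(config: PhantomConfig) -> SyntheticCase:
    """Generate a complete synthetic case: phantom, doses, TLDs, truncation."""
    ct, structures, density = generate_phantom(config)
    case = SyntheticCase(config=config, ct=ct, density=density, structures=structures)
    generate_csi_dose(case, config)

    body = structures["whole body"]
    voxel_cm3 = float(np.prod(config.spacing)) / 1000.0
    mass_kg = float(density.values[body].sum() * voxel_cm3 / 1000.0)
    case.truncation = TruncationInfo(
        mass_in_image_kg=mass_kg,
        total_body_mass_kg=mass_kg / config.truncation_ratio,
        applies_to=frozenset(TRUNCATION_ORGANS),
    )
    if config.modality == "photon":
        for organ in DEFAULT_TLD_ORGANS:
            case.measurements.extend(generate_tld_measurements(case, organ))
    return case
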