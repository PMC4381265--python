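"""HDF5 case container and CSV table I/O.

Container layout::

    /ct                      CT-number grid
    /density                 mass density grid (g/cm^3)
    /masks/<organ>           boolean organ masks
    /dose/<component>        dose grids, each with a `unit` attribute
    /surfaces/<level>        isodose surface vertex lists (n, 3) in mm
    /bnv_mask                beam normalization volume (proton cases)
    measurements             table of (organ, x_mm, y_mm, z_mm, H_Sv)

Grid spacing/origin and the generating configuration live in root
attributes.  Dose component names carry ``/sp`` for per-source-particle
grids; the slash is escaped as ``|`` inside HDF5 paths.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grids import DensityGrid, DoseGrid, StructureSet, TruncationInfo
from .out_of_field import IsodoseSurface, PointMeasurement
from .phantom import PhantomConfig, SyntheticCase

__all__ = ["save_case", "load_case", "write_organ_doses", "read_organ_doses"]


def _escape(name: str) -> str:
    return name.replace("/", "|")


def _unescape(name: str) -> str:
    return name.replace("|", "/")


def save_case(case: SyntheticCase, path: str | Path) -> None:
    """Write a complete case to an HDF5 container."""
    cfg = dataclasses.asdict(case.config)
    with h5py.File(path, "w") as f:
        f.attrs["spacing"] = case.config.spacing
        f.attrs["origin"] = case.config.origin
        f.attrs["config"] = json.dumps(cfg)
        f.create_dataset("ct", data=case.ct, compression="gzip")
        f.create_dataset("density", data=case.density.values, compression="gzip")
        g = f.create_group("masks")
        for organ, mask in case.structures.masks.items():
            g.create_dataset(_escape(organ), data=mask, compression="gzip")
        g = f.create_group("dose")
        for name, grid in case.dose.items():
            d = g.create_dataset(_escape(name), data=grid.values, compression="gzip")
            d.attrs["unit"] = grid.unit
        g = f.create_group("surfaces")
        for level, surf in case.surfaces.items():
            g.create_dataset(f"{level:g}", data=surf.vertices)
        if case.bnv_mask is not None:
            f.create_dataset("bnv_mask", data=case.bnv_mask, compression="gzip")
        if case.truncation is not None:
            f.attrs["mass_in_image_kg"] = case.truncation.mass_in_image_kg
            f.attrs["total_body_mass_kg"] = case.truncation.total_body_mass_kg
            f.attrs["truncation_applies_to"] = json.dumps(
                sorted(case.truncation.applies_to)
            )
        if case.measurements:
            rows = [
                (m.organ, *m.position_mm, m.H_Sv) for m in case.measurements
            ]
            rec = np.array(
                rows,
                dtype=[
                    ("organ", "S64"),
                    ("x_mm", "f8"),
                    ("y_mm", "f8"),
                    ("z_mm", "f8"),
                    ("H_Sv", "f8"),
                ],
            )
            f.create_dataset("measurements", data=rec)


def load_case(path: str | Path) -> SyntheticCase:
    """Read a case container back into memory."""
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        for key in ("shape", "spacing", "origin", "spinal_z_mm",
                    "neutron_organ_mean_range"):
            if key in cfg_dict and isinstance(cfg_dict[key], list):
                cfg_dict[key] = tuple(cfg_dict[key])
        config = PhantomConfig(**cfg_dict)
        spacing = tuple(f.attrs["spacing"])
        origin = tuple(f.attrs["origin"])
        density = DensityGrid(
            values=f["density"][()], spacing=spacing, origin=origin
        )
        masks = {
            _unescape(k): f["masks"][k][()].astype(bool) for k in f["masks"]
        }
        case = SyntheticCase(
            config=config,
            ct=f["ct"][()],
            density=density,
            structures=StructureSet(masks=masks),
        )
        for k in f["dose"]:
            d = f["dose"][k]
            case.dose[_unescape(k)] = DoseGrid(
                values=d[()], spacing=spacing, origin=origin,
                unit=d.attrs["unit"],
            )
        for k in f.get("surfaces", {}):
            case.surfaces[float(k)] = IsodoseSurface(
                level=float(k), vertices=f["surfaces"][k][()]
            )
        if "bnv_mask" in f:
            case.bnv_mask = f["bnv_mask"][()].astype(bool)
        if "mass_in_image_kg" in f.attrs:
            case.truncation = TruncationInfo(
                mass_in_image_kg=float(f.attrs["mass_in_image_kg"]),
                total_body_mass_kg=float(f.attrs["total_body_mass_kg"]),
                applies_to=frozenset(
                    json.loads(f.attrs["truncation_applies_to"])
                ),
            )
        if "measurements" in f:
            for row in f["measurements"][()]:
                case.measurements.append(
                    PointMeasurement(
                        organ=row["organ"].decode(),
                        position_mm=(row["x_mm"], row["y_mm"], row["z_mm"]),
                        H_Sv=float(row["H_Sv"]),
                    )
                )
    return case


def write_organ_doses(df: pd.DataFrame, path: str | Path) -> None:
    """Organ-dose table to CSV (index column `organ`), round-trippable."""
    df.to_csv(path, index=True)


def read_organ_doses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
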