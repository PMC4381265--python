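"""Secondary-neutron dose handling for proton CSI.

Passively scattered proton therapy produces stray neutrons in the treatment
unit ("external") and in the patient ("internal").  Monte Carlo transport
reports their equivalent dose per source particle; this module combines the
two components, and rescales per-source-particle output to the therapeutic
prescription through a beam normalization volume (BNV) — a contoured region
of approximately uniform in-field dose whose planning-system dose anchors
the number of source particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .constants import W_R_NEUTRON_EXTERNAL, W_R_NEUTRON_INTERNAL

__all__ = [
    "NeutronWeights",
    "NormalizationInputs",
    "FieldDoseSet",
    "combine_neutron_components",
    "total_organ_dose",
    "normalize_to_prescription",
    "sum_over_fields",
]


@dataclass(frozen=True)
class NeutronWeights:
    """Mean radiation weighting factors for stray neutrons.

    Single scalar values adopted from Monte Carlo studies of similarly sized
    patients (not energy-dependent spectra): 9.2 for external neutrons, 9.0
    for internal neutrons.
    """

    w_R_ext: float = W_R_NEUTRON_EXTERNAL
    w_R_int: float = W_R_NEUTRON_INTERNAL

    def __post_init__(self):
        if self.w_R_ext <= 1 or self.w_R_int <= 1:
            raise ValueError(
                "neutron weighting factors must exceed 1 (neutrons are high-LET)"
            )


@dataclass(frozen=True)
class NormalizationInputs:
    """Quantities needed to scale per-source-particle doses to prescription.

    ``source_particles`` is derived: the number of source particles that makes
    the Monte Carlo BNV primary dose match the planning system's BNV dose.
    """

    H_per_sp: float  # organ equivalent dose per source particle, Sv/sp
    H_BNV_pri_per_sp: float  # BNV primary equivalent dose per sp, Sv/sp
    H_BNV_pri_TPS: float  # BNV primary equivalent dose from the TPS, Sv

    def __post_init__(self):
        if self.H_BNV_pri_per_sp <= 0:
            raise ValueError("BNV per-source-particle dose must be positive")
        if self.H_per_sp < 0 or self.H_BNV_pri_TPS < 0:
            raise ValueError("doses must be non-negative")

    @property
    def source_particles(self) -> float:
        return self.H_BNV_pri_TPS / self.H_BNV_pri_per_sp


@dataclass
class FieldDoseSet:
    """Per-treatment-field organ dose components.

    ``fields`` maps field name -> DataFrame indexed by organ with one column
    per dose component; all fields must share organ list and components.
    """

    fields: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        frames = list(self.fields.values())
        if frames:
            ref = frames[0]
            for name, df in self.fields.items():
                if not df.index.equals(ref.index) or list(df.columns) != list(
                    ref.columns
                ):
                    raise ValueError(
                        f"field {name!r} has a mismatched organ list or "
                        "component set"
                    )


def combine_neutron_components(H_ext: float, H_int: float) -> float:
    """Total neutron organ dose: external plus internal contributions (Sv)."""
    if H_ext < 0 or H_int < 0:
        raise ValueError("neutron dose components must be non-negative")
    return H_ext + H_int


def total_organ_dose(H_primary: float, H_ext: float, H_int: float) -> float:
    """Total organ equivalent dose: therapeutic primary + both neutron parts."""
    if H_primary < 0:
        raise ValueError("primary dose must be non-negative")
    return H_primary + combine_neutron_components(H_ext, H_int)


def normalize_to_prescription(inputs: NormalizationInputs) -> float:
    """Scale a per-source-particle organ dose to the delivered prescription.

    H_T = (H_T/sp) x source_particles, with source_particles fixed by
    requiring the Monte Carlo BNV primary dose to reproduce the
    planning-system BNV dose.  Invariant under rescaling the source-particle
    normalisation of both Monte Carlo quantities.
    """
    return inputs.H_per_sp * inputs.source_particles


def sum_over_fields(fields: FieldDoseSet) -> pd.DataFrame:
    """Componentwise sum of organ doses over all treatment fields."""
    if not fields.fields:
        raise ValueError("no treatment fields given")
    frames = list(fields.fields.values())
    total = frames[0].copy()
    for df in frames[1:]:
        total += df
    return total
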