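"""Lifetime attributable second-cancer risk projection.

Risk follows a linear-no-threshold (LNT) model: the excess absolute lifetime
risk of incidence and mortality at each cancer site is the product of a
site-specific risk coefficient (%/Sv) and the mean equivalent dose of the
driving organ (Sv):

    I_T = (I_T / H_T) * H_T      M_T = (M_T / H_T) * H_T

Coefficients come from BEIR-VII-style endpoint tables, linearly interpolated
in age, with the dose and dose-rate effectiveness factor (DDREF, 1.5)
removed for all sites except leukemia because therapeutic doses are far above
the low-dose regime the DDREF corrects for.  Non-melanoma skin cancer (NMSC)
uses pre-derived ICRP-60-based coefficients; thyroid mortality is incidence
times a 0.1 lethality fraction.  Site-to-organ mapping: other solid cancers
take the "remainder" dose and leukemia the red-bone-marrow dose.

An immediate consequence of LNT is that per-site proton:photon risk ratios
equal the corresponding organ dose ratios, identically for incidence and
mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    DDREF,
    RISK_SITES,
    SITE_TO_ORGAN,
    THYROID_LETHALITY,
    reference_risk_coefficients,
)

__all__ = [
    "RiskCoefficientTable",
    "RiskReport",
    "interpolate_coefficients",
    "remove_ddref",
    "thyroid_mortality_coefficient",
    "lifetime_risk",
    "site_risks",
    "aggregate_and_ratio",
    "attribute_components",
]


@dataclass(frozen=True)
class RiskCoefficientTable:
    """Per-site incidence and mortality risk coefficients (%/Sv).

    ``coefficients`` is indexed by cancer site with columns ``I_over_H`` and
    ``M_over_H``.  ``ddref_removed`` records whether the DDREF uplift has
    already been applied (guards against applying it twice).
    """

    coefficients: pd.DataFrame
    age: float
    sex: str = "female"
    ddref_removed: bool = False

    def __post_init__(self):
        df = self.coefficients
        missing = {"I_over_H", "M_over_H"} - set(df.columns)
        if missing:
            raise ValueError(f"coefficient table lacks columns {sorted(missing)}")
        if (df[["I_over_H", "M_over_H"]] < 0).any().any():
            raise ValueError("risk coefficients must be non-negative")

    @property
    def sites(self) -> list[str]:
        return list(self.coefficients.index)

    @classmethod
    def reference(cls) -> "RiskCoefficientTable":
        """The packaged table for a 13-year-old girl (DDREF already removed)."""
        return cls(
            coefficients=reference_risk_coefficients(),
            age=13.0,
            sex="female",
            ddref_removed=True,
        )


@dataclass(frozen=True)
class RiskReport:
    """Per-site and aggregate lifetime risks with proton:photon ratios.

    ``per_site`` columns: I/M risks (%) per modality, per-site ratios.
    ``aggregates``: summed incidence incl./excl. NMSC and summed mortality
    per modality.  ``ratios``: proton/photon for each aggregate.
    ``attribution``: per-modality dose-component risk fractions.
    """

    per_site: pd.DataFrame
    aggregates: dict[str, float]
    ratios: dict[str, float]
    attribution: dict[str, dict[str, float]] = field(default_factory=dict)


def interpolate_coefficients(
    table_a: RiskCoefficientTable,
    table_b: RiskCoefficientTable,
    age: float,
) -> RiskCoefficientTable:
    """Linear age interpolation between two coefficient tables.

    Typically bracketing endpoint ages (e.g. 10 and 15 years) around the
    patient age; no extrapolation is allowed.
    """
    if table_a.age >= table_b.age:
        raise ValueError("table_a must be for the younger age")
    if not table_a.age <= age <= table_b.age:
        raise ValueError(
            f"age {age} outside the interpolation range "
            f"[{table_a.age}, {table_b.age}]"
        )
    if table_a.sites != table_b.sites:
        raise ValueError("coefficient tables cover different site lists")
    if table_a.ddref_removed != table_b.ddref_removed:
        raise ValueError("tables disagree on DDREF state")
    w = (age - table_a.age) / (table_b.age - table_a.age)
    coeff = (1 - w) * table_a.coefficients + w * table_b.coefficients
    return RiskCoefficientTable(
        coefficients=coeff,
        age=age,
        sex=table_a.sex,
        ddref_removed=table_a.ddref_removed,
    )


def remove_ddref(
    table: RiskCoefficientTable,
    factor: float = DDREF,
    exempt: frozenset[str] | set[str] = frozenset({"leukemia"}),
) -> RiskCoefficientTable:
    """Undo the DDREF reduction: multiply coefficients by ``factor``.

    Leukemia is exempt (its BEIR VII model carries no DDREF).  Refuses to run
    twice on the same table.
    """
    if table.ddref_removed:
        raise ValueError("DDREF has already been removed from this table")
    coeff = table.coefficients.copy()
    scale = pd.Series(
        [1.0 if s in exempt else factor for s in coeff.index], index=coeff.index
    )
    coeff = coeff.mul(scale, axis=0)
    return replace(table, coefficients=coeff, ddref_removed=True)


def thyroid_mortality_coefficient(
    I_thyroid_over_H: float, lethality: float = THYROID_LETHALITY
) -> float:
    """Thyroid mortality coefficient from incidence via the lethality fraction."""
    if not 0 <= lethality <= 1:
        raise ValueError("lethality fraction must lie in [0, 1]")
    if I_thyroid_over_H < 0:
        raise ValueError("incidence coefficient must be non-negative")
    return I_thyroid_over_H * lethality


def lifetime_risk(coefficient: float, H_T: float) -> float:
    """LNT lifetime risk (%): coefficient (%/Sv) times organ dose (Sv)."""
    if coefficient < 0 or H_T < 0:
        raise ValueError("coefficient and dose must be non-negative")
    return coefficient * H_T


def site_risks(
    organ_doses: Mapping[str, float] | pd.Series,
    table: RiskCoefficientTable,
    site_to_organ: Mapping[str, str] = SITE_TO_ORGAN,
) -> pd.DataFrame:
    """Per-site incidence and mortality risks (%) from organ doses (Sv)."""
    rows = {}
    for site in table.sites:
        organ = site_to_organ.get(site, site)
        if organ not in organ_doses:
            raise KeyError(f"no dose available for organ {organ!r} (site {site!r})")
        H = float(organ_doses[organ])
        rows[site] = (
            lifetime_risk(table.coefficients.at[site, "I_over_H"], H),
            lifetime_risk(table.coefficients.at[site, "M_over_H"], H),
            H,
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["I", "M", "H_T"])
    df.index.name = "site"
    return df


def aggregate_and_ratio(
    proton_doses: Mapping[str, float] | pd.Series,
    photon_doses: Mapping[str, float] | pd.Series,
    table: RiskCoefficientTable,
    site_to_organ: Mapping[str, str] = SITE_TO_ORGAN,
) -> RiskReport:
    """Full risk comparison between the proton and photon dose tables.

    Builds per-site risks per modality, sums incidence (with and without
    NMSC) and mortality, and forms proton:photon ratios for each aggregate
    and per site.  Per-site incidence and mortality ratios coincide (both
    equal the organ dose ratio under LNT).
    """
    proton = site_risks(proton_doses, table, site_to_organ)
    photon = site_risks(photon_doses, table, site_to_organ)
    if list(proton.index) != list(photon.index):
        raise ValueError("modalities cover different site lists")

    per_site = pd.DataFrame(
        {
            "H_proton_Sv": proton["H_T"],
            "H_photon_Sv": photon["H_T"],
            "I_proton_pct": proton["I"],
            "I_photon_pct": photon["I"],
            "M_proton_pct": proton["M"],
            "M_photon_pct": photon["M"],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site["I_ratio"] = per_site["I_proton_pct"] / per_site["I_photon_pct"]
        per_site["M_ratio"] = per_site["M_proton_pct"] / per_site["M_photon_pct"]

    def _agg(df: pd.DataFrame) -> tuple[float, float, float]:
        incl = df["I"].sum()
        excl = incl - df.at["nmsc", "I"] if "nmsc" in df.index else incl
        return incl, excl, df["M"].sum()

    Ip, Ip_x, Mp = _agg(proton)
    Ix, Ix_x, Mx = _agg(photon)
    aggregates = {
        "I_proton_incl_nmsc": Ip,
        "I_proton_excl_nmsc": Ip_x,
        "M_proton": Mp,
        "I_photon_incl_nmsc": Ix,
        "I_photon_excl_nmsc": Ix_x,
        "M_photon": Mx,
    }
    ratios = {
        "incidence_incl_nmsc": Ip / Ix,
        "incidence_excl_nmsc": Ip_x / Ix_x,
        "mortality": Mp / Mx,
    }
    return RiskReport(per_site=per_site, aggregates=aggregates, ratios=ratios)


def attribute_components(
    dose_components: pd.DataFrame,
    table: RiskCoefficientTable,
    site_to_organ: Mapping[str, str] = SITE_TO_ORGAN,
    total_column: str = "total",
    endpoint: str = "I",
    rtol: float = 0.02,
) -> dict[str, float]:
    """Fraction of total risk attributable to each dose component.

    ``dose_components`` is indexed by organ with one column per component
    plus a ``total`` column.  For component c:

        fraction_c = sum_sites coeff * H_c / sum_sites coeff * H_total

    Fractions over an exhaustive component set sum to 1.  ``endpoint`` picks
    the incidence ("I") or mortality ("M") coefficients.
    """
    components = [c for c in dose_components.columns if c != total_column]
    sums = dose_components[components].sum(axis=1)
    totals = dose_components[total_column]
    if not np.allclose(sums, totals, rtol=rtol, atol=1e-9):
        raise ValueError("dose components do not sum to the stated totals")
    col = {"I": "I_over_H", "M": "M_over_H"}[endpoint]
    denom = 0.0
    numer = {c: 0.0 for c in components}
    for site in table.sites:
        organ = site_to_organ.get(site, site)
        coeff = table.coefficients.at[site, col]
        denom += coeff * float(totals[organ])
        for c in components:
            numer[c] += coeff * float(dose_components.at[organ, c])
    if denom <= 0:
        raise ValueError("total risk is zero; attribution undefined")
    return {c: numer[c] / denom for c in components}
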