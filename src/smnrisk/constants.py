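"""Bundled reference-case constants.

The package ships the inputs of a fully worked reference case: a 13-year-old
girl prescribed 23.4 Gy-RBE craniospinal irradiation (CSI), planned once with
passively scattered protons and once with 6-MV photons at a second
institution.  The constants below are the published mean organ equivalent
doses and the BEIR-VII-derived lifetime risk coefficients for that case; they
let the risk engine be exercised (and regression-tested) without any dose
grids at all.

Units: organ doses in Sv; risk coefficients in % per Sv (absolute lifetime
risk per 100 persons per sievert).
"""

from __future__ import annotations

import pandas as pd

#: Prescribed dose to the craniospinal axis, Gy-RBE (1.8 Gy-RBE x 13 fractions).
D_RX_GY_RBE = 23.4

#: Mean radiation weighting factors.
W_R_PHOTON = 1.0
W_R_PROTON = 1.1  # RBE of therapeutic protons; 23.4 Gy-RBE <-> 21.3 Gy
W_R_NEUTRON_EXTERNAL = 9.2  # neutrons made in the treatment unit
W_R_NEUTRON_INTERNAL = 9.0  # neutrons made in the patient

#: Ratio of imaged body mass to whole-body mass for the reference patient;
#: applied to volumes that extend beyond the CT image (mid-thigh cut-off).
TRUNCATION_RATIO = 0.726
TRUNCATION_ORGANS = frozenset(
    {"red bone marrow", "skin", "remainder", "whole body"}
)

#: DDREF removed from BEIR VII coefficients at therapeutic dose levels.
DDREF = 1.5
#: ICRP-60 lethality fraction for thyroid cancer (mortality = incidence x this).
THYROID_LETHALITY = 0.1

#: Two-Gaussian out-of-field dose model, fitted for the photon CSI treatment
#: unit: absorbed dose per unit prescribed dose (cGy/Gy) vs. distance r (cm)
#: from the 50% isodose surface.  (alpha_i in cm*cGy/Gy, mu_i and sigma_i in cm.)
OUT_OF_FIELD_PARAMS = {
    "alpha1": 224.8,
    "mu1": -2.16,
    "sigma1": 1.57,
    "alpha2": 224.3,
    "mu2": -7.43,
    "sigma2": 10.28,
}

#: Cancer sites carrying a risk coefficient, and the contoured organ whose
#: mean equivalent dose drives each site.
SITE_TO_ORGAN = {
    "stomach": "stomach",
    "colon": "colon",
    "liver": "liver",
    "lung": "lungs",
    "breast": "breasts",
    "uterus": "uterus",
    "ovary": "ovaries",
    "bladder": "bladder",
    "thyroid": "thyroid",
    "leukemia": "red bone marrow",
    "nmsc": "skin",
    "other solid": "remainder",
}

RISK_SITES = tuple(SITE_TO_ORGAN)

#: Contoured volumes of the reference structure set.  "remainder" is the
#: Boolean subtraction of the union of the specific SMN-site organs from the
#: whole body.  Rectum is contoured but carries no site-specific coefficient.
ORGAN_LIST = (
    "whole body",
    "bladder",
    "breasts",
    "colon",
    "liver",
    "lungs",
    "ovaries",
    "skin",
    "stomach",
    "thyroid",
    "uterus",
    "rectum",
    "red bone marrow",
    "remainder",
)

#: Specific SMN-site organs subtracted from the whole body to form "remainder".
SPECIFIC_ORGANS = tuple(
    o for o in ORGAN_LIST if o not in ("whole body", "remainder")
)


def reference_risk_coefficients() -> pd.DataFrame:
    """Lifetime risk coefficients for a 13-year-old girl, DDREF removed.

    Incidence (``I_over_H``) and mortality (``M_over_H``) in %/Sv, linearly
    interpolated between the BEIR VII 10- and 15-year-old female values (NMSC
    from ICRP 60; thyroid mortality = incidence x 0.1 lethality).
    """
    data = {
        "stomach": (0.98, 0.55),
        "colon": (2.15, 1.00),
        "liver": (0.26, 0.23),
        "lung": (6.78, 5.96),
        "breast": (9.25, 2.17),
        "uterus": (0.49, 0.11),
        "ovary": (0.98, 0.54),
        "bladder": (2.07, 0.58),
        "thyroid": (3.25, 0.33),
        "leukemia": (0.80, 0.52),
        "nmsc": (17.77, 0.04),
        "other solid": (6.82, 2.93),
    }
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=["I_over_H", "M_over_H"]
    )
    df.index.name = "site"
    return df


def reference_proton_doses() -> pd.DataFrame:
    """Mean organ equivalent doses (Sv) for the reference proton CSI plan.

    Components: therapeutic protons (``primary``), neutrons produced in the
    treatment unit (``external neutron``) and in the patient
    (``internal neutron``); ``total`` is their sum.
    """
    rows = {
        "stomach": (0.01, 0.34, 0.14),
        "colon": (0.08, 0.27, 0.11),
        "liver": (0.39, 0.38, 0.12),
        "lungs": (1.82, 0.48, 0.17),
        "breasts": (0.00, 0.32, 0.07),
        "uterus": (0.00, 0.21, 0.08),
        "ovaries": (0.00, 0.18, 0.07),
        "bladder": (0.00, 0.13, 0.06),
        "thyroid": (0.45, 0.44, 0.31),
        "red bone marrow": (4.41, 0.24, 0.14),
        "skin": (2.40, 0.27, 0.12),
        "remainder": (2.84, 0.27, 0.16),
        "whole body": (2.52, 0.27, 0.15),
    }
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["primary", "external neutron", "internal neutron"],
    )
    df.index.name = "organ"
    df["total"] = df.sum(axis=1)
    return df


def reference_photon_doses() -> pd.DataFrame:
    """Mean organ equivalent doses (Sv) for the reference photon CSI plan.

    One column per out-of-field estimation approach: planning-system values
    only (``tps``), volume-weighted averaging with phantom point measurements
    for fully out-of-field organs (``volume-weighted``), and analytic
    replacement of far out-of-field voxels (``model``).  The ``model`` column
    is the one used for risk projection.
    """
    rows = {
        "stomach": (9.48, 9.48, 9.73),
        "colon": (6.12, 6.12, 6.82),
        "liver": (4.64, 4.64, 5.33),
        "lungs": (4.78, 4.78, 5.59),
        "breasts": (0.72, 0.72, 1.57),
        "uterus": (0.02, 0.60, 1.11),
        "ovaries": (0.02, 0.60, 1.70),
        "bladder": (0.03, 0.60, 1.10),
        "thyroid": (16.75, 16.75, 16.75),
        "red bone marrow": (5.49, 5.49, 5.88),
        "skin": (2.58, 2.58, 2.80),
        "remainder": (4.77, 4.77, 4.91),
        "whole body": (4.53, 4.53, 4.64),
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["tps", "volume-weighted", "model"]
    )
    df.index.name = "organ"
    return df
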