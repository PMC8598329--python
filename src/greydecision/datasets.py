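"""Bundled worked example: cardiovascular mortality determinants across the
eight SAARC countries, annual data 2001-2017.

These tables are the printed results of a published grey-system analysis of
CVD mortality and six socioeconomic factors (urbanization, population
growth, HDI, access to energy, unemployment, public health expenditure)
in Pakistan, Bangladesh, Maldives, Afghanistan, Nepal, India, Sri Lanka and
Bhutan. The underlying raw indicator series are not redistributable, so the
example ships the derived quantities: the grey incidence degree table, the
crisp decision matrix, the per-country conservative aggregates, the
ideal/anti-ideal interval patterns, and the D+/D- distance matrices of the
grey TOPSIS stage. They serve as fixture inputs for the arithmetic the
package reimplements.

Known internal inconsistencies of the source tables (kept verbatim, not
repaired):

* The Pakistan/HDI degree row (AD 0.85553, DD 0.85463, SSD 0.85005) does
  not satisfy the SSD = (AD + DD)/2 relation that every other row obeys
  (the mean is 0.85508) and duplicates the Maldives/population-growth
  AD/DD values; see :data:`ANOMALOUS_SYNTHESIS_PAIRS`.
* Two decision-matrix cells differ from the degree table
  (urbanization/Bangladesh 0.83546 vs 0.85558; urbanization/Bhutan
  0.84463 vs 0.85963).
* The published per-country aggregate vector has 0.85005 in the Pakistan
  slot, while the column maximum of the decision matrix's Pakistan column
  is 0.87709; with the matrix as shipped, the conservative min-max selects
  Afghanistan at 0.85007 instead.
* The published HDI assessment degree (0.723) is not reproducible from the
  shipped distance rows, which give 0.639 under the closeness formula that
  reproduces the other five factors; see
  :data:`NONREPRODUCIBLE_ASSESSMENT_FACTORS`.
"""

from __future__ import annotations

import pandas as pd

from .decision import DecisionMatrix
from .topsis import GreyNumber

COUNTRIES = (
    "Pakistan",
    "Bangladesh",
    "Maldives",
    "Afghanistan",
    "Nepal",
    "India",
    "Sri Lanka",
    "Bhutan",
)

FACTORS = (
    "urbanization",
    "population_growth",
    "hdi",
    "access_to_energy",
    "unemployment",
    "public_health_expenditure",
)

#: (factor, country) pairs whose degree row breaks the synthesis relation.
ANOMALOUS_SYNTHESIS_PAIRS = {("hdi", "Pakistan")}

#: Factors whose published assessment degree cannot be recomputed from the
#: shipped distance rows.
NONREPRODUCIBLE_ASSESSMENT_FACTORS = {"hdi"}

# factor -> country -> (ad_gia, dd_gia, ssd_gia)
_GIA_DEGREES = {
    "urbanization": {
        "Pakistan": (0.87375, 0.84687, 0.86031),
        "Bangladesh": (0.87066, 0.84049, 0.85558),
        "Maldives": (0.65430, 0.59470, 0.62450),
        "Afghanistan": (0.79400, 0.63250, 0.71325),
        "Nepal": (0.86190, 0.84497, 0.85347),
        "India": (0.80245, 0.77141, 0.78693),
        "Sri Lanka": (0.81105, 0.79009, 0.80057),
        "Bhutan": (0.86823, 0.85103, 0.85963),
    },
    "population_growth": {
        "Pakistan": (0.82650, 0.71666, 0.77158),
        "Bangladesh": (0.68830, 0.62008, 0.65419),
        "Maldives": (0.85553, 0.85463, 0.85508),
        "Afghanistan": (0.71475, 0.69743, 0.70609),
        "Nepal": (0.75313, 0.64587, 0.69950),
        "India": (0.80301, 0.70099, 0.75200),
        "Sri Lanka": (0.90675, 0.89745, 0.90210),
        "Bhutan": (0.90537, 0.81245, 0.85891),
    },
    "hdi": {
        "Pakistan": (0.85553, 0.85463, 0.85005),
        "Bangladesh": (0.81113, 0.74103, 0.77608),
        "Maldives": (0.62390, 0.59880, 0.61135),
        "Afghanistan": (0.88526, 0.81476, 0.85001),
        "Nepal": (0.76514, 0.70098, 0.73306),
        "India": (0.80374, 0.79906, 0.80140),
        "Sri Lanka": (0.61047, 0.54369, 0.57708),
        "Bhutan": (0.76115, 0.63845, 0.69980),
    },
    "access_to_energy": {
        "Pakistan": (0.88981, 0.85005, 0.86993),
        "Bangladesh": (0.79610, 0.76610, 0.78110),
        "Maldives": (0.82483, 0.77333, 0.79908),
        "Afghanistan": (0.73696, 0.68696, 0.71196),
        "Nepal": (0.80117, 0.79977, 0.80047),
        "India": (0.78159, 0.71239, 0.74699),
        "Sri Lanka": (0.85886, 0.84128, 0.85007),
        "Bhutan": (0.85225, 0.81291, 0.83258),
    },
    "unemployment": {
        "Pakistan": (0.83824, 0.78990, 0.81407),
        "Bangladesh": (0.88259, 0.84467, 0.86363),
        "Maldives": (0.73609, 0.65473, 0.69541),
        "Afghanistan": (0.81723, 0.75009, 0.78366),
        "Nepal": (0.72285, 0.69993, 0.71139),
        "India": (0.90180, 0.89934, 0.90057),
        "Sri Lanka": (0.90916, 0.86730, 0.88823),
        "Bhutan": (0.72846, 0.73654, 0.73250),
    },
    "public_health_expenditure": {
        "Pakistan": (0.91079, 0.84339, 0.87709),
        "Bangladesh": (0.87679, 0.83269, 0.85474),
        "Maldives": (0.81736, 0.71650, 0.76693),
        "Afghanistan": (0.82849, 0.79245, 0.81047),
        "Nepal": (0.83660, 0.74300, 0.78980),
        "India": (0.93063, 0.84783, 0.88923),
        "Sri Lanka": (0.86548, 0.81458, 0.84003),
        "Bhutan": (0.74542, 0.65472, 0.70007),
    },
}

# factor rows x country columns, as published (differs from the degree
# table in two urbanization cells; see module docstring).
_DECISION_MATRIX = {
    "urbanization": (0.86031, 0.83546, 0.62450, 0.71325, 0.85347, 0.78693, 0.80057, 0.84463),
    "population_growth": (0.77158, 0.65419, 0.85508, 0.70609, 0.69950, 0.75200, 0.90210, 0.85891),
    "hdi": (0.85005, 0.77608, 0.61135, 0.85007, 0.73306, 0.80140, 0.57708, 0.69980),
    "access_to_energy": (0.86993, 0.78110, 0.79908, 0.71196, 0.80047, 0.74699, 0.85007, 0.83258),
    "unemployment": (0.81407, 0.86363, 0.69541, 0.78366, 0.71139, 0.90057, 0.88823, 0.73250),
    "public_health_expenditure": (0.87709, 0.85474, 0.76693, 0.81047, 0.78980, 0.88923, 0.84003, 0.70007),
}

#: Published per-country aggregates fed to the conservative min-max rule.
_COUNTRY_AGGREGATES = (0.85005, 0.86363, 0.85508, 0.85007, 0.85347, 0.90057, 0.90210, 0.85891)

# Ideal / anti-ideal interval patterns per country column.
_IDEAL = (
    (0.55, 0.65), (0.42, 0.67), (0.54, 0.88), (0.40, 0.65),
    (0.42, 0.60), (0.55, 0.91), (0.52, 0.86), (0.45, 0.77),
)
_ANTI_IDEAL = (
    (0.23, 0.25), (0.18, 0.34), (0.20, 0.43), (0.10, 0.15),
    (0.17, 0.15), (0.26, 0.56), (0.20, 0.46), (0.16, 0.17),
)

# Distance rows (factor x country) from the ideal (D+) and anti-ideal (D-).
_D_PLUS = {
    "urbanization": (0.23, 0.09, 0.32, 0.05, 0.14, 0.00, 0.00, 0.39),
    "population_growth": (0.00, 0.23, 0.18, 0.40, 0.28, 0.32, 0.36, 0.19),
    "hdi": (0.00, 0.27, 0.07, 0.03, 0.11, 0.12, 0.18, 0.00),
    "access_to_energy": (0.31, 0.00, 0.34, 0.04, 0.28, 0.00, 0.11, 0.06),
    "unemployment": (0.28, 0.27, 0.14, 0.00, 0.13, 0.23, 0.28, 0.12),
    "public_health_expenditure": (0.12, 0.21, 0.24, 0.00, 0.23, 0.00, 0.12, 0.19),
}
_D_MINUS = {
    "urbanization": (0.14, 0.20, 0.08, 0.35, 0.01, 0.12, 0.15, 0.00),
    "population_growth": (0.36, 0.06, 0.22, 0.00, 0.12, 0.06, 0.00, 0.00),
    "hdi": (0.36, 0.02, 0.33, 0.38, 0.00, 0.00, 0.16, 0.13),
    "access_to_energy": (0.04, 0.29, 0.06, 0.36, 0.00, 0.24, 0.00, 0.19),
    "unemployment": (0.14, 0.02, 0.13, 0.12, 0.00, 0.03, 0.11, 0.00),
    "public_health_expenditure": (0.24, 0.16, 0.17, 0.06, 0.19, 0.00, 0.30, 0.21),
}

#: Published grey synthetic assessment degrees (three decimals). The hdi
#: value is the non-reproducible one.
PUBLISHED_ASSESSMENT = {
    "urbanization": 0.463,
    "population_growth": 0.295,
    "hdi": 0.723,
    "access_to_energy": 0.509,
    "unemployment": 0.275,
    "public_health_expenditure": 0.545,
}

#: Published SSD-based ranking of countries within each factor, best first.
PUBLISHED_COUNTRY_RANKINGS = {
    "urbanization": (
        "Pakistan", "Bhutan", "Bangladesh", "Nepal",
        "Sri Lanka", "India", "Afghanistan", "Maldives",
    ),
    "population_growth": (
        "Sri Lanka", "Bhutan", "Maldives", "Pakistan",
        "India", "Afghanistan", "Nepal", "Bangladesh",
    ),
    "hdi": (
        "Pakistan", "Afghanistan", "India", "Bangladesh",
        "Nepal", "Bhutan", "Maldives", "Sri Lanka",
    ),
    "access_to_energy": (
        "Pakistan", "Sri Lanka", "Bhutan", "Nepal",
        "Maldives", "Bangladesh", "India", "Afghanistan",
    ),
    "unemployment": (
        "India", "Sri Lanka", "Bangladesh", "Pakistan",
        "Afghanistan", "Bhutan", "Nepal", "Maldives",
    ),
    "public_health_expenditure": (
        "India", "Pakistan", "Bangladesh", "Sri Lanka",
        "Afghanistan", "Nepal", "Maldives", "Bhutan",
    ),
}

#: Published factor ordering from the grey TOPSIS stage, best first.
PUBLISHED_FACTOR_ORDER = (
    "hdi",
    "public_health_expenditure",
    "access_to_energy",
    "urbanization",
    "population_growth",
    "unemployment",
)


def load_example_gia_table() -> pd.DataFrame:
    """48-row degree table: factor, country, ad_gia, dd_gia, ssd_gia."""
    rows = [
        (factor, country, *_GIA_DEGREES[factor][country])
        for factor in FACTORS
        for country in COUNTRIES
    ]
    return pd.DataFrame(
        rows, columns=["factor", "country", "ad_gia", "dd_gia", "ssd_gia"]
    )


def load_example_decision_matrix() -> DecisionMatrix:
    """6 x 8 crisp decision matrix, factor rows x country columns."""
    frame = pd.DataFrame(
        [_DECISION_MATRIX[f] for f in FACTORS],
        index=list(FACTORS),
        columns=list(COUNTRIES),
    )
    return DecisionMatrix(frame)


def load_example_country_aggregates() -> pd.Series:
    """Published per-country aggregate degrees fed to min-max selection."""
    return pd.Series(_COUNTRY_AGGREGATES, index=list(COUNTRIES), dtype=float)


def load_example_ideal_patterns():
    """(ideal, anti_ideal) GreyNumber Series per country column.

    Shape/format fixture only: these intervals depend on the source's
    unstated linguistic scale and weights and cannot be regenerated from
    the crisp matrix.
    """
    index = pd.Index(list(COUNTRIES))
    ideal = pd.Series([GreyNumber(*g) for g in _IDEAL], index=index, dtype=object)
    anti = pd.Series([GreyNumber(*g) for g in _ANTI_IDEAL], index=index, dtype=object)
    return ideal, anti


def load_example_distances():
    """(d_plus, d_minus) factor x country distance frames."""
    d_plus = pd.DataFrame(
        [_D_PLUS[f] for f in FACTORS], index=list(FACTORS), columns=list(COUNTRIES)
    )
    d_minus = pd.DataFrame(
        [_D_MINUS[f] for f in FACTORS], index=list(FACTORS), columns=list(COUNTRIES)
    )
    return d_plus, d_minus
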