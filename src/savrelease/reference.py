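"""Reference calibration data for the three benchmark formulations.

Literature-reported characterisation of three FDM-printed tablet
formulations spanning matrix types and drug solubility classes:

* ``PVA-PDM`` — pramipexole dihydrochloride monohydrate (BCS I) in a
  water-soluble polyvinyl-alcohol hydrocolloid matrix,
* ``EVA-LD``  — levodopa (BCS I) in an inert ethylene-vinyl-acetate matrix,
* ``PVA-PZQ`` — praziquantel (BCS II) in polyvinyl alcohol.

The tables hold the printed geometry characteristics (surface area, volume,
SA/V ratio, dose and mean dissolution time per design), the reported
MDT–SA/V power laws with their out-of-sample validation rows, and the
release-equation constants per SA/V level that drive the synthetic-data
archetypes.  Geometry dimensions were not reported; the
:data:`INFERRED_DIMENSIONS` entries are reverse-engineered so that their
closed-form SA and V reproduce the tabulated values and are marked verified
only where that reproduction is exact.
"""

from __future__ import annotations

FORMULATIONS = ("PVA-PDM", "EVA-LD", "PVA-PZQ")

#: reported MDT = A * (SA/V)^p laws: formulation -> (A in min, p)
MDT_POWER_LAWS: dict[str, tuple[float, float]] = {
    "PVA-PDM": (62.5, -1.3),
    "EVA-LD": (209.43, -1.71),
    "PVA-PZQ": (73.487, -1.145),
}

#: drug mass fraction of the filament per formulation
DRUG_LOAD_FRACTION: dict[str, float] = {
    "PVA-PDM": 0.05,
    "EVA-LD": 0.10,
    "PVA-PZQ": 0.05,
}

#: geometry characterisation of the PVA-PDM formulation.
#: rows: (group SA/V level, form, SA mm^2, V mm^3, SA/V mm^-1, dose mg,
#:        MDT min, f2 vs the group's cylinder or None for the reference)
GEOMETRY_TABLE: list[tuple[float, str, float, float, float, float, float, float | None]] = [
    (1.0, "Q1", 606.00, 585.00, 1.00, 35.97, 56.95, 77.51),
    (1.0, "Q2", 256.00, 256.00, 1.00, 15.60, 62.91, 87.92),
    (1.0, "Q3", 250.00, 250.00, 1.00, 15.66, 65.65, 73.88),
    (1.0, "HC", 667.59, 667.59, 1.00, 41.34, 56.84, 71.87),
    (1.0, "C", 201.06, 201.06, 1.00, 12.29, 60.67, None),
    (1.0, "P", 273.05, 265.97, 1.03, 16.25, 64.30, 82.89),
    (1.5, "Q1", 546.00, 360.00, 1.52, 21.74, 32.81, 78.20),
    (1.5, "Q2", 192.00, 128.00, 1.50, 8.00, 35.67, 92.54),
    (1.5, "Q3", 166.00, 110.00, 1.51, 6.92, 38.07, 73.19),
    (1.5, "HC", 301.59, 201.06, 1.50, 13.54, 33.83, 90.82),
    (1.5, "C", 150.80, 100.53, 1.50, 6.19, 34.80, None),
    (1.5, "P", 121.92, 80.10, 1.52, 4.85, 36.92, 75.40),
    (2.0, "Q1", 516.00, 247.50, 2.08, 15.04, 22.98, 66.45),
    (2.0, "Q2", 169.60, 83.20, 2.04, 5.21, 25.70, 96.55),
    (2.0, "Q3", 142.00, 70.00, 2.03, 4.43, 24.90, 91.95),
    (2.0, "HC", 201.06, 100.50, 2.00, 6.87, 25.02, 92.37),
    (2.0, "C", 133.20, 65.35, 2.04, 3.92, 25.14, None),
    (2.0, "P", 66.02, 32.24, 2.05, 1.99, 24.86, 75.79),
]


def geometry_group_mdts(group_sav: float) -> list[float]:
    """Reported per-design MDTs of one SA/V group of the geometry table."""
    return [row[6] for row in GEOMETRY_TABLE if row[0] == group_sav]


#: dimensions (mm) reverse-engineered from the tabulated SA and V; verified
#: entries reproduce the table row exactly with the closed-form formulas
INFERRED_DIMENSIONS: dict[tuple[float, str], dict] = {
    (1.0, "C"): {"family": "cylinder", "dimensions": {"r": 4.0, "h": 4.0}, "verified": True},
    (1.0, "Q2"): {"family": "cuboid", "dimensions": {"a": 8.0, "b": 8.0, "c": 4.0}, "verified": True},
    (1.5, "C"): {"family": "cylinder", "dimensions": {"r": 4.0, "h": 2.0}, "verified": True},
    (1.5, "Q2"): {"family": "cuboid", "dimensions": {"a": 8.0, "b": 8.0, "c": 2.0}, "verified": True},
    (2.0, "Q2"): {"family": "cuboid", "dimensions": {"a": 8.0, "b": 8.0, "c": 1.3}, "verified": True},
    # Q1/Q3/HC/P dimensions are not uniquely recoverable from SA and V alone
}

#: out-of-sample MDT validation: formulation ->
#: rows (SA/V mm^-1, predicted MDT min, measured mean min, measured sd min, RMSEP min)
MDT_VALIDATION: dict[str, list[tuple[float, float, float, float, float]]] = {
    "PVA-PDM": [
        (0.90, 71.70, 74.06, 11.45, 2.36),
        (1.60, 33.83, 31.04, 2.20, 2.79),
        (2.30, 21.07, 16.65, 0.46, 4.42),
        (4.67, 8.36, 6.93, 0.71, 1.43),
    ],
    "EVA-LD": [
        (1.73, 82.25, 78.79, 7.24, 3.46),
        (1.89, 70.74, 62.60, 5.90, 8.14),
        (4.67, 15.13, 14.40, 0.77, 0.73),
    ],
    "PVA-PZQ": [
        (1.30, 54.42, 55.91, 1.11, 1.49),
        (1.83, 36.79, 38.73, 1.07, 1.94),
        (2.30, 28.32, 27.88, 2.23, 0.44),
        (4.67, 12.58, 12.16, 0.96, 0.42),
    ],
}

#: Peppas-Sahlin constants per SA/V level (shared exponent fits):
#: formulation -> {SA/V: (k1 %/min^n, k2 %/min^2n)}
PEPPAS_SAHLIN_CONSTANTS: dict[str, dict[float, tuple[float, float]]] = {
    "PVA-PDM": {
        0.8: (1.986, 0.010),
        1.0: (2.516, 0.011),
        1.5: (3.920, 0.027),
        2.0: (5.561, 0.067),
        2.5: (7.362, 0.135),
        3.3: (11.555, 0.258),
        4.0: (15.459, 0.545),
        5.0: (16.888, 0.713),
        6.0: (20.856, 1.069),
    },
    "EVA-LD": {
        0.9: (1.952, 0.010),
        1.1: (2.286, 0.014),
        1.5: (3.115, 0.020),
        1.7: (4.087, 0.031),
        1.9: (5.009, 0.053),
        2.5: (7.636, 0.153),
        4.0: (10.374, 0.279),
        5.0: (14.444, 0.540),
        6.0: (16.816, 0.727),
    },
}

#: shared diffusion exponent n_bar of the Peppas-Sahlin fits per formulation
SHARED_EXPONENT: dict[str, float] = {
    "PVA-PDM": 0.79,
    "EVA-LD": 0.66,
}

#: Weibull constants per SA/V level: formulation -> {SA/V: (a min, b)}
WEIBULL_CONSTANTS: dict[str, dict[float, tuple[float, float]]] = {
    "PVA-PZQ": {
        0.8: (105.0, 1.38),
        1.0: (81.0, 1.45),
        1.5: (52.0, 1.63),
        2.0: (38.0, 1.80),
        2.5: (31.5, 1.91),
        3.3: (20.8, 2.05),
        4.0: (17.1, 2.15),
        5.0: (11.5, 2.29),
        6.0: (11.2, 2.40),
    },
}
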