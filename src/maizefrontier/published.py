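"""Published reference constants used as default inputs by downstream stages.

These are the reporting-surface numbers of the synthesis study this package
re-implements: the most-frequent planting windows per latitude group, the
variance-component table for the contest-winner database, and the frontier
parameters of the literature / contest boundary fits.  They are *inputs*
(e.g. the default window table for before/within/after comparisons), never
asserted as outputs of this package's own estimators.
"""

from __future__ import annotations

#: latitude-group labels, degrees N, south to north
LATITUDE_GROUPS = ("25-30", "30-35", "35-40", "40-45", "45-50")

#: most frequent planting window (DOY, both ends inclusive) per latitude
#: group, as reported from the geospatial frequency analysis
MOST_FREQUENT_WINDOWS: dict[str, tuple[int, int]] = {
    "25-30": (42, 88),
    "30-35": (89, 106),
    "35-40": (107, 118),
    "40-45": (119, 128),
    "45-50": (129, 135),
}

#: the six fixed planting-date map classes (DOY, inclusive); the last is
#: open-ended.  Note the 45-50N class here (129-148) differs from the
#: most-frequent window above (129-135); both are retained.
FIXED_DOY_CLASSES: tuple[tuple[int, int | None], ...] = (
    (42, 88), (89, 106), (107, 118), (119, 128), (129, 148), (149, None),
)

#: global very-early/early/medium/late planting classes (DOY, inclusive)
VE_ER_MD_LT_CLASSES: dict[str, tuple[int, int]] = {
    "VE": (42, 88),
    "ER": (89, 106),
    "MD": (107, 118),
    "LT": (119, 128),
}

#: per-factor variance components, (Mg ha^-1)^2, for the contest database
VARIANCE_COMPONENTS: dict[str, float] = {
    "year": 0.1816,
    "state": 0.1706,
    "irrigation": 0.0010,
    "planting_date": 0.0403,
    "seeding_rate": 0.0010,
    "row_spacing": 0.0097,
    "tillage": 0.0010,
    "nitrogen": 0.0022,
    "phosphorus": 0.0031,
    "potash": 0.0000,
    "error_interaction": 4.9841,
}

#: published total yield variance, (Mg ha^-1)^2
TOTAL_VARIANCE = 5.3945263

#: boundary (0.99-quantile linear-plateau) parameters of the two source
#: datasets: plateau in Mg ha^-1, breakpoint in DOY
FRONTIER_PARAMETERS: dict[str, dict[str, float]] = {
    "contest": {"plateau": 21.0, "breakpoint": 152.0},
    "literature": {"plateau": 18.0, "breakpoint": 123.0},
}

#: sample sizes of the two source datasets
DATASET_SIZES = {"contest": 16171, "literature": 819}
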