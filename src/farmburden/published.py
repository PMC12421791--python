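"""Published summary values for Australian on-farm injury, 2013–2023.

These are the printed aggregates from the national surveillance sources
(coronial fatality records and workers' compensation claims) that the
package uses in two ways:

* as calibration targets for the synthetic registry generator, and
* as inputs to :mod:`farmburden.verify`, which replays every piece of
  arithmetic connecting them (shares, divide-and-round annual means,
  column sums, coverage scaling).

Counts of fewer than five cases are suppressed in the source ("np") and
some larger cells are masked ("+") to prevent recovery by subtraction;
masked cells are recorded here as ``None``.  Monetary values are AUD.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Fatalities, 2013–2023 (11 calendar years)
# --------------------------------------------------------------------------

N_FATALITIES = 748
N_WORK_RELATED = 544
N_NON_WORK = 203
N_UNKNOWN_WORK_STATUS = 1          # one case still under investigation
N_MALE_WORK_RELATED = 513
N_WORK_AGED_60_PLUS = 249
FATALITY_YEARS = 11
FATALITY_YEAR_RANGE = (2013, 2023)

#: Agent of fatal injury by work status: (non_work, work, total) per agent,
#: grouped into the six major agent groups plus "unknown".  ``None`` marks a
#: suppressed ("np") or complementarily masked ("+") cell; totals are always
#: published except for the single unknown case.
FATALITY_AGENT_TABLE: dict[str, dict[str, tuple[int | None, int | None, int]]] = {
    "farm_vehicles": {
        "quad": (32, 85, 117),
        "utility": (33, 19, 52),
        "ssv": (28, 16, 44),
        "motorbike": (16, 13, 29),
        "car": (None, None, 16),
        "helicopter": (0, 15, 15),
        "truck": (None, None, 15),
        "fixed_wing_aircraft": (None, None, 12),
        "trailer": (None, None, 11),
        "gyrocopter": (0, 6, 6),
        "other": (None, None, 10),
    },
    "mobile_machinery": {
        "tractor": (6, 112, 118),
        "forklift": (None, None, 12),
        "bobcat": (None, None, 8),
        "bulldozer": (None, None, 8),
        "harvesting_machine": (0, 8, 8),
        "slasher_mower_conditioner": (0, 6, 6),
        "telehandler": (0, 6, 6),
        "other": (None, None, 40),
    },
    "farm_structures": {
        "dam_creek_river": (None, None, 19),
        "powerlines": (None, None, 8),
        "water_tank": (None, None, 7),
        "other_shed": (None, None, 5),
        "other": (None, None, 17),
    },
    "working_environment": {
        "trees_felling": (6, 12, 18),
        "trees_not_felling": (None, None, 14),
        "fire_smoke_flame": (0, 11, 11),
        "other": (None, None, 13),
    },
    "animal": {
        "horse": (16, 13, 29),
        "cattle": (0, 14, 14),
        "other": (None, None, 12),
    },
    "other": {
        "firearms": (None, None, 6),
        "other": (6, 35, 41),
    },
    "unknown": {
        "unknown": (None, None, 1),
    },
}

FATALITY_AGENT_GROUP_TOTALS = {
    "farm_vehicles": 327,
    "mobile_machinery": 206,
    "farm_structures": 56,
    "working_environment": 56,
    "animal": 55,
    "other": 47,
    "unknown": 1,
}

#: The six leading individual agents and their published counts.
LEADING_AGENT_COUNTS = {
    "tractor": 118,
    "quad": 117,
    "utility": 52,
    "ssv": 44,
    "horse": 29,
    "motorbike": 29,
}

#: Age-band cost summary (2023 AUD): band label -> (n cases, total $, average $).
#: Totals and averages are published rounded to the nearest $5,000.
AGE_BAND_COSTS: dict[str, tuple[int, int, int]] = {
    "<15": (87, 172_540_000, 1_985_000),
    "15-24": (61, 196_070_000, 3_215_000),
    "25-34": (68, 328_350_000, 4_830_000),
    "35-44": (72, 281_800_000, 3_915_000),
    "45-54": (99, 348_470_000, 3_520_000),
    "55-64": (125, 257_455_000, 2_060_000),
    ">=65": (236, 194_995_000, 825_000),
}
AGE_BAND_TOTAL_ROW = (748, 1_780_000_000, 2_380_000)

TOTAL_FATALITY_COST = 1_780_000_000          # ~$1.8B, all cases, 2023 AUD
WORK_RELATED_FATALITY_COST = 1_240_000_000   # $1.24B, work-related cases
HEADLINE_TOTAL_COST = 1.8e9                  # the abstract's "almost $1.8 billion"
ANNUAL_FATALITY_COST_M = 164                 # $M/year, all cases
ANNUAL_WORK_FATALITY_COST_M = 112            # $M/year, narrative figure

# --------------------------------------------------------------------------
# Workers' compensation claims, financial years 2013–14 .. 2021–22
# --------------------------------------------------------------------------

FIN_YEARS_PERIOD_1 = ["2013-14", "2014-15", "2015-16", "2016-17"]
FIN_YEARS_PERIOD_2 = ["2017-18", "2018-19", "2019-20", "2020-21", "2021-22"]
FIN_YEARS = FIN_YEARS_PERIOD_1 + FIN_YEARS_PERIOD_2
#: Years for which claim cost/time data are available (eight years).
COST_FIN_YEARS = FIN_YEARS_PERIOD_1 + ["2017-18", "2018-19", "2019-20", "2020-21"]

#: Claim counts by severity and period: (period total, published annual mean).
#: Published figures are rounded to the nearest 5.
CLAIMS_BY_SEVERITY = {
    ("minor", "period_1"): (9_280, 2_320),
    ("serious", "period_1"): (10_900, 2_725),
    ("total", "period_1"): (20_185, 5_045),
    ("minor", "period_2"): (10_220, 2_045),
    ("serious", "period_2"): (14_385, 2_875),
    ("total", "period_2"): (24_605, 4_920),
}

#: Agency of injury major group -> (period-1 total, %, annual mean,
#:                                  period-2 total, %, annual mean).
CLAIMS_BY_AGENCY: dict[str, tuple[int, int, int, int, int, int]] = {
    "animal_human_biological": (4_430, 22, 1_110, 5_260, 21, 1_050),
    "chemicals_chemical_products": (335, 2, 85, 370, 2, 75),
    "environmental_agencies": (3_055, 15, 765, 4_155, 17, 830),
    "machinery_fixed_plant": (1_185, 6, 295, 1_490, 6, 300),
    "materials_substances": (2_575, 13, 645, 3_185, 13, 635),
    "mobile_plant_transport": (2_620, 13, 655, 3_055, 12, 610),
    "nonpowered_handtools_equipment": (3_799, 19, 925, 4_265, 17, 855),
    "other_unspecified": (1_695, 8, 425, 2_060, 8, 410),
    "powered_equipment_tools": (590, 3, 145, 765, 3, 155),
}

AGENCY_GROUPS = list(CLAIMS_BY_AGENCY)

#: fin_year -> (total weeks lost, % of weeks, total cost $, % of cost).
CLAIMS_TIME_COST_BY_YEAR: dict[str, tuple[int, int, int, int]] = {
    "2013-14": (55_460, 11, 167_965_000, 11),
    "2014-15": (54_575, 11, 160_655_000, 11),
    "2015-16": (63_895, 13, 222_090_000, 15),
    "2016-17": (66_250, 13, 215_060_000, 14),
    "2017-18": (72_140, 14, 226_480_000, 15),
    "2018-19": (65_730, 13, 198_585_000, 13),
    "2019-20": (66_060, 13, 171_384_000, 11),
    "2020-21": (58_540, 12, 144_145_000, 10),
}
CLAIMS_WEEKS_SUBTOTALS = (240_180, 262_470)
CLAIMS_COST_SUBTOTALS = (765_770_000, 740_595_000)   # 2nd printed row is 1,000 above the cell sum
CLAIMS_WEEKS_TOTAL = 502_650
CLAIMS_COST_TOTAL = 1_505_000_000                    # grand total, rounded to nearest $5M

#: Serious-claim (5+ days lost) medians per fin_year: (weeks, cost $).
SERIOUS_CLAIM_MEDIANS: dict[str, tuple[float, int]] = {
    "2013-14": (5.4, 9_310),
    "2014-15": (5.2, 8_950),
    "2015-16": (6.0, 11_320),
    "2016-17": (6.5, 12_250),
    "2017-18": (6.9, 13_230),
    "2018-19": (6.4, 12_830),
    "2019-20": (6.6, 12_660),
    "2020-21": (6.8, 12_430),
}
SERIOUS_MEDIAN_WEEKS = 6.3
SERIOUS_MEDIAN_COST = 11_750

ANNUAL_CLAIMS_COST_M = 190          # $M/year direct claim costs
SERIOUS_COST_SHARE = 0.95           # serious claims carry ~95% of claim cost

# --------------------------------------------------------------------------
# Coverage / scaling
# --------------------------------------------------------------------------

COVERAGE_FRACTION = 0.58            # share of the farm workforce covered
UNDER_COVERAGE_FACTOR = 0.4         # published multiplicative uplift
SCALED_ANNUAL_CLAIMS_COST_M = 265   # 190 x 1.4, nearest 5
COMBINED_ANNUAL_COST_M = 355        # fatalities + claims, nearest 5
COMBINED_WORK_ANNUAL_COST_M = 300   # work-related portion, nearest 5
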