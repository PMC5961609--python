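"""Published summary statistics of the 2011 EFUS winter monitoring sample.

The 2011 Energy Follow-Up Survey (EFUS), linked to the English Housing
Survey, monitored indoor temperatures in n=635 English homes in three rooms
at 20-minute cadence over February 2011, December 2011 and January 2012.
The raw logger panel is private; the aggregate values below are published
sample characteristics and headline results. They serve two purposes here:

* as realistic default composition for the synthetic-data generator
  (regional / dwelling-type / tenure mix, LTD and age prevalences), and
* as worked-example inputs for arithmetic that needs only the published
  aggregates (room-mean contrasts, night-criterion shares, relative risk
  from group proportions).
"""

from __future__ import annotations

N_DWELLINGS = 635
N_LTD = 369          # households reporting one or more long-term disabilities
N_OVER64 = 206       # households whose oldest member is 65 or older

#: Sample counts by Government Office Region.
REGION_COUNTS = {
    "North East": 44,
    "North West": 103,
    "Yorkshire & Humber": 83,
    "East Midlands": 53,
    "West Midlands": 58,
    "East": 88,
    "London": 46,
    "South East": 101,
    "South West": 59,
}

DWELLING_TYPE_COUNTS = {
    "Detached": 153,
    "Semi-detached": 204,
    "Terraced": 178,
    "Purpose-built flat": 86,
    "Converted flat": 14,
}

TENURE_COUNTS = {
    "Owned outright": 192,
    "Owned with mortgage": 211,
    "Rented from council": 82,
    "Social rented: other": 94,
    "Private rented": 56,
}

#: Households in which each long-term disability type was reported
#: (multiple types per household possible; 581 occurrences across 369 homes).
LTD_TYPE_COUNTS = {
    "Vision": 28,
    "Hearing": 24,
    "Learning": 12,
    "Heart": 75,
    "Breathing": 92,
    "Mobility": 146,
    "Mental": 35,
    "Other": 165,
    "Don't know": 4,
}

#: Winter mean temperature per room across the sample, °C (mean, SD).
ROOM_MEANS_C = {
    "bedroom": (18.15, 2.51),
    "living_room": (18.90, 2.46),
    "hallway": (18.25, 2.57),
}

#: Dwellings meeting ≥9 h at ≥18 °C at night, and dwellings below 1 h.
NIGHT_CRITERION_MET = 247
NIGHT_BELOW_1H = 101

#: Share of households with ≥90% of days at the 18 °C criterion, by LTD group (%).
PCT_DAYS90_LTD = 26.8
PCT_DAYS90_NO_LTD = 20.7
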