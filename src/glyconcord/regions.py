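"""World regions used to group studies.

The grouping follows the eight-region convention common in pooled analyses
of cardiometabolic surveys.  Surveys measuring both fasting plasma glucose
(FPG) and HbA1c exist in seven of the eight regions; Oceania is part of the
enumeration but holds no studies under the default generator configuration.
"""

from __future__ import annotations

from enum import Enum


class Region(str, Enum):
    CENTRAL_EASTERN_EUROPE = "central_eastern_europe"
    CENTRAL_ASIA_MIDDLE_EAST_NORTH_AFRICA = "central_asia_middle_east_north_africa"
    HIGH_INCOME_WESTERN = "high_income_western"
    LATIN_AMERICA_CARIBBEAN = "latin_america_caribbean"
    SOUTH_ASIA = "south_asia"
    EAST_SOUTHEAST_ASIA_PACIFIC = "east_southeast_asia_pacific"
    SUB_SAHARAN_AFRICA = "sub_saharan_africa"
    OCEANIA = "oceania"


#: Regions populated with studies by default (all except Oceania).
DEFAULT_POPULATED_REGIONS: tuple[Region, ...] = tuple(
    r for r in Region if r is not Region.OCEANIA
)

#: Reference region for regression contrasts.
REFERENCE_REGION = Region.HIGH_INCOME_WESTERN
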