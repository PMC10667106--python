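"""Diagnostic thresholds and canonical column names shared across modules."""

#: Diabetes threshold for fasting plasma glucose, mmol/L.
FPG_THRESHOLD = 7.0
#: Diabetes threshold for HbA1c, % (NGSP).
HBA1C_THRESHOLD = 6.5

#: Mandatory columns of a participant table, in canonical order.
PARTICIPANT_COLUMNS = [
    "participant_id",
    "study_id",
    "sex",
    "age",
    "bmi",
    "fpg",
    "hba1c",
    "diagnosed_previously",
    "on_glucose_lowering_medication",
    "pregnant",
    "visit_index",
]

#: Mandatory columns of a study-metadata table.
STUDY_COLUMNS = [
    "study_id",
    "region",
    "mid_year",
    "fpg_portable",
    "hba1c_portable",
    "fpg_capillary",
    "capillary_plasma_equivalent",
]

SEX_VALUES = ("female", "male")
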