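"""Canonical column naming shared by every module.

The structural feature table always carries exactly 33 measures in a fixed
order: 5 callosal partition volumes (anterior to posterior), then the 7
corpus-callosum tract segments (cc1 = rostrum ... cc7 = splenium) for each
microstructural family FA, MD, NDI, ODI.  All downstream matrices index
columns through these constants, never by position literals.
"""

from __future__ import annotations

SEGMENTS = tuple(range(1, 8))

VOLUME_COLUMNS = (
    "volume_anterior",
    "volume_mid_anterior",
    "volume_central",
    "volume_mid_posterior",
    "volume_posterior",
)
FA_COLUMNS = tuple(f"fa_cc{i}" for i in SEGMENTS)
MD_COLUMNS = tuple(f"md_cc{i}" for i in SEGMENTS)
NDI_COLUMNS = tuple(f"ndi_cc{i}" for i in SEGMENTS)
ODI_COLUMNS = tuple(f"odi_cc{i}" for i in SEGMENTS)

#: The canonical 33-column structural order used everywhere.
STRUCTURAL_COLUMNS = VOLUME_COLUMNS + FA_COLUMNS + MD_COLUMNS + NDI_COLUMNS + ODI_COLUMNS

#: Measure families in canonical order.
FAMILIES = {
    "volume": VOLUME_COLUMNS,
    "fa": FA_COLUMNS,
    "md": MD_COLUMNS,
    "ndi": NDI_COLUMNS,
    "odi": ODI_COLUMNS,
}

#: Reverse lookup measure -> family name.
FAMILY_OF = {col: fam for fam, cols in FAMILIES.items() for col in cols}

#: Required clinical columns (analysed; missing values are not permitted).
CLINICAL_REQUIRED = (
    "subject_id",
    "group",
    "sex",
    "age_months",
    "ga_weeks",
    "iq",
    "wm_raw",
    "ps_raw",
    "inh_raw",
    "affect_raw",
    "tom_raw",
)

#: Optional clinical columns.
CLINICAL_OPTIONAL = ("birth_weight_g", "ses")

#: Fixed order of the clinical analysis matrix X (8 columns, or 9 with ses).
X_COLUMNS = (
    "age_months",
    "ga_weeks",
    "iq",
    "wm",
    "ps",
    "inhibition",
    "affect_recognition",
    "theory_of_mind",
)
X_COLUMNS_SES = X_COLUMNS + ("ses",)

#: Raw clinical column feeding each residualized X column.
RESIDUALIZED_SOURCE = {
    "wm": "wm_raw",
    "ps": "ps_raw",
    "inhibition": "inh_raw",
    "affect_recognition": "affect_raw",
    "theory_of_mind": "tom_raw",
}

GROUPS = ("VPT", "FT")
SEXES = ("F", "M")
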