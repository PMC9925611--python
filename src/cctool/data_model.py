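"""Cohort table types, validation, and delimited-text I/O.

Two per-subject tables describe a cohort:

* a clinical table — group membership (very preterm ``VPT`` vs full-term
  ``FT``), sex, age at assessment, gestational age, and six raw
  neuropsychological scores, plus optional birth weight and socio-economic
  (Largo) score;
* a structural table — the 33 corpus-callosum measures (5 partition volumes
  and 7 tract segments x {FA, MD, NDI, ODI}) in the canonical order of
  :data:`cctool.columns.STRUCTURAL_COLUMNS`.

Both are stored as UTF-8 comma-separated text with a header row.  Mean
diffusivity is expressed in units of 1e-3 mm^2/s so typical values are of
order one.  Missing values are not permitted in analysed columns; subjects
with any missing analysed value are dropped at load time with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .columns import (
    CLINICAL_OPTIONAL,
    CLINICAL_REQUIRED,
    GROUPS,
    SEXES,
    STRUCTURAL_COLUMNS,
)

logger = logging.getLogger(__name__)

AGE_RANGE_MONTHS = (60.0, 200.0)
GA_VPT_MAX = 32.0
GA_FT_RANGE = (37.0, 42.0)
SES_RANGE = (0.0, 12.0)


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed header."""


class ValidationError(ValueError):
    """A table value violates a domain invariant."""


def _check_unique_ids(df: pd.DataFrame, label: str) -> None:
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{label} table has duplicate subject_id(s): {sorted(set(dup))}"
        )


@dataclass
class ClinicalTable:
    """Per-subject clinical and neuropsychological record."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in CLINICAL_REQUIRED if c not in self.df.columns]
        if missing:
            raise SchemaError(f"clinical table missing column(s): {missing}")
        _check_unique_ids(self.df, "clinical")
        for sid, row in self.df.set_index("subject_id").iterrows():
            if row["group"] not in GROUPS:
                raise ValidationError(f"subject {sid}: group {row['group']!r} not in {GROUPS}")
            if row["sex"] not in SEXES:
                raise ValidationError(f"subject {sid}: sex {row['sex']!r} not in {SEXES}")
            age = row["age_months"]
            if not AGE_RANGE_MONTHS[0] <= age <= AGE_RANGE_MONTHS[1]:
                raise ValidationError(
                    f"subject {sid}: age_months {age} outside {AGE_RANGE_MONTHS}"
                )
            ga = row["ga_weeks"]
            if row["group"] == "VPT" and not ga < GA_VPT_MAX:
                raise ValidationError(f"subject {sid}: VPT ga_weeks {ga} not < {GA_VPT_MAX}")
            if row["group"] == "FT" and not GA_FT_RANGE[0] <= ga <= GA_FT_RANGE[1]:
                raise ValidationError(
                    f"subject {sid}: FT ga_weeks {ga} outside {GA_FT_RANGE}"
                )
            if not row["iq"] > 0:
                raise ValidationError(f"subject {sid}: iq {row['iq']} must be > 0")
            if "ses" in self.df.columns and pd.notna(row.get("ses")):
                if not SES_RANGE[0] <= row["ses"] <= SES_RANGE[1]:
                    raise ValidationError(
                        f"subject {sid}: ses {row['ses']} outside {SES_RANGE}"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])

    @property
    def n(self) -> int:
        return len(self.df)

    def group_rows(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]


@dataclass
class StructuralTable:
    """Per-subject 33 callosal structural measures in canonical order."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ("subject_id", *STRUCTURAL_COLUMNS) if c not in self.df.columns]
        if missing:
            raise SchemaError(f"structural table missing column(s): {missing}")
        _check_unique_ids(self.df, "structural")
        vals = self.df.set_index("subject_id")[list(STRUCTURAL_COLUMNS)]
        for fam_prefix in ("fa_", "ndi_", "odi_"):
            cols = [c for c in STRUCTURAL_COLUMNS if c.startswith(fam_prefix)]
            bad = vals[cols][(vals[cols] < 0) | (vals[cols] > 1)].stack()
            if len(bad):
                sid, col = bad.index[0]
                raise ValidationError(
                    f"subject {sid}: {col} = {bad.iloc[0]} outside [0, 1]"
                )
        for fam_prefix in ("md_", "volume_"):
            cols = [c for c in STRUCTURAL_COLUMNS if c.startswith(fam_prefix)]
            bad = vals[cols][vals[cols] <= 0].stack()
            if len(bad):
                sid, col = bad.index[0]
                raise ValidationError(f"subject {sid}: {col} = {bad.iloc[0]} must be > 0")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"])

    @property
    def n(self) -> int:
        return len(self.df)

    def measures(self) -> pd.DataFrame:
        """The n x 33 measure block indexed by subject_id, canonical order."""
        return self.df.set_index("subject_id")[list(STRUCTURAL_COLUMNS)]


def _read_table(path: str | Path, required: tuple[str, ...], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path.name} missing column(s): {missing}")
    analysed = [c for c in df.columns if c in required and c != "subject_id"]
    before = len(df)
    df = df.dropna(subset=analysed).reset_index(drop=True)
    if len(df) < before:
        logger.warning(
            "%s: dropped %d subject(s) with missing analysed values", label, before - len(df)
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def load_cohort(
    clinical_path: str | Path, structural_path: str | Path
) -> tuple[ClinicalTable, StructuralTable]:
    """Read and validate the two cohort CSV files.

    Headers are matched case-insensitively against the canonical names.
    Subjects with missing analysed values are dropped with a logged count.
    The subject_id sets of the two tables must overlap.
    """
    cdf = _read_table(clinical_path, CLINICAL_REQUIRED, "clinical")
    sdf = _read_table(structural_path, ("subject_id", *STRUCTURAL_COLUMNS), "structural")
    clinical = ClinicalTable(cdf)
    structural = StructuralTable(sdf)
    common = set(clinical.subject_ids) & set(structural.subject_ids)
    if not common:
        raise ValidationError("clinical and structural tables share no subject_id")
    return clinical, structural


def write_cohort(
    clinical: ClinicalTable, structural: StructuralTable, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the cohort as clinical.csv / structural.csv with canonical headers.

    Values are serialized at full precision so a reload reproduces the tables
    exactly.  Optional columns absent from the table are not written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ccols = [c for c in (*CLINICAL_REQUIRED, *CLINICAL_OPTIONAL) if c in clinical.df.columns]
    cpath = out_dir / "clinical.csv"
    spath = out_dir / "structural.csv"
    # shortest decimal that round-trips the double exactly
    fmt = lambda v: repr(float(v))
    clinical.df[ccols].to_csv(cpath, index=False, float_format=fmt)
    structural.df[["subject_id", *STRUCTURAL_COLUMNS]].to_csv(
        spath, index=False, float_format=fmt
    )
    return cpath, spath


def align_by_subject(clinical: ClinicalTable, structural: StructuralTable) -> pd.DataFrame:
    """Inner-join the two tables on subject_id.

    Row order follows the clinical table restricted to the intersection; the
    number of dropped subjects is logged.  An empty intersection is an error.
    """
    merged = clinical.df.merge(structural.df, on="subject_id", how="inner", sort=False)
    dropped = len(clinical.df) + len(structural.df) - 2 * len(merged)
    if merged.empty:
        raise ValidationError("no subjects shared between clinical and structural tables")
    if dropped:
        logger.warning("align_by_subject: dropped %d unmatched subject(s)", dropped)
    return merged
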