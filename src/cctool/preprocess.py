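"""Build the clinical analysis matrix X and structural matrix Y.

The clinical matrix has the fixed column order age, gestational age, IQ,
then the five age-residualized scores (working memory, processing speed,
inhibition, affect recognition, theory of mind), optionally followed by the
socio-economic (Largo) score.  Age, gestational age and IQ pass through
unchanged — IQ instruments are already age-standardized — while the five raw
scores are regressed on age at assessment within the analysed group and the
standardized residuals retained.

Processing speed keeps its natural sign (a reaction time; larger = slower);
any "faster processing" reading belongs to interpretation, not the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .columns import RESIDUALIZED_SOURCE, STRUCTURAL_COLUMNS, X_COLUMNS, X_COLUMNS_SES
from .data_model import ClinicalTable, StructuralTable, ValidationError, align_by_subject


@dataclass
class AnalysisMatrices:
    """Paired analysis matrices for one group.

    X is n x p (p = 8, or 9 with SES); Y is n x 33 in canonical structural
    order.  Residualized X columns have mean 0 and sample SD 1 within the
    analysed group.
    """

    X: np.ndarray
    Y: np.ndarray
    row_ids: list[str]
    x_names: list[str]
    y_names: list[str]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValidationError("analysis matrices contain non-finite entries")


def age_residualize(scores: np.ndarray, ages: np.ndarray, name: str = "score") -> np.ndarray:
    """Standardized residuals of an OLS simple regression of score on age.

    Residuals are divided by their sample SD (denominator n-1), so the output
    has mean 0 and SD 1.  Constant ages or zero-variance residuals (scores an
    exact linear function of age) are errors.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if scores.shape != ages.shape or scores.ndim != 1:
        raise ValueError("scores and ages must be matching 1-d arrays")
    if len(scores) < 3:
        raise ValueError(f"{name}: need at least 3 subjects to residualize")
    if np.ptp(ages) == 0:
        raise ValueError(f"{name}: ages are constant, cannot regress on age")
    slope, intercept = np.polyfit(ages, scores, 1)
    resid = scores - (intercept + slope * ages)
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(scores.std(ddof=1), 1e-300):
        raise ValueError(f"{name}: residuals have zero variance (score linear in age)")
    return resid / sd


def inhibition_score(acc_incongruent: float, acc_congruent: float) -> float:
    """Accuracy difference: incongruent minus congruent condition."""
    for label, v in (("acc_incongruent", acc_incongruent), ("acc_congruent", acc_congruent)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{label} = {v} outside [0, 1]")
    return acc_incongruent - acc_congruent


def build_matrices(
    clinical: ClinicalTable,
    structural: StructuralTable,
    group: str = "all",
    include_ses: bool = False,
) -> AnalysisMatrices:
    """Assemble X (clinical) and Y (structural) for one analysis group.

    Residualization on age is computed within the selected group, matching the
    group-wise analysis design.  ``group`` is "VPT", "FT" or "all".
    """
    if group not in ("VPT", "FT", "all"):
        raise ValueError(f"group must be VPT, FT or all, got {group!r}")
    merged = align_by_subject(clinical, structural)
    if group != "all":
        merged = merged[merged["group"] == group].reset_index(drop=True)
    if merged.empty:
        raise ValidationError(f"no subjects in requested group {group!r}")

    ages = merged["age_months"].to_numpy(float)
    cols: dict[str, np.ndarray] = {
        "age_months": ages,
        "ga_weeks": merged["ga_weeks"].to_numpy(float),
        "iq": merged["iq"].to_numpy(float),
    }
    for xname, raw in RESIDUALIZED_SOURCE.items():
        cols[xname] = age_residualize(merged[raw].to_numpy(float), ages, name=raw)
    x_names = list(X_COLUMNS)
    if include_ses:
        if "ses" not in merged.columns or merged["ses"].isna().any():
            raise ValidationError("include_ses requested but ses is missing")
        cols["ses"] = merged["ses"].to_numpy(float)
        x_names = list(X_COLUMNS_SES)

    X = np.column_stack([cols[c] for c in x_names])
    Y = merged[list(STRUCTURAL_COLUMNS)].to_numpy(float)
    return AnalysisMatrices(
        X=X,
        Y=Y,
        row_ids=list(merged["subject_id"]),
        x_names=x_names,
        y_names=list(STRUCTURAL_COLUMNS),
    )
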