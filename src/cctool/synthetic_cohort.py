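"""Synthetic FT/VPT cohort generator with known ground truth.

The generator emulates the *derived* feature tables of a preterm-birth
neurodevelopment study — per-subject clinical scores and 33 corpus-callosum
tractometry/volumetry measures — not raw MRI.  Its statistical skeleton:

* ages uniform on the study range (72–173 months by default);
* gestational age drawn per group (full-term ~ N(39.83, 1.33) truncated to
  [37, 42] weeks; very preterm ~ N(29.59, 1.73) truncated below 32 weeks);
* each structural measure = family baseline (at a 120-month reference age)
  + family maturation slope x (age - 120)
  + [VPT only] - deviation_rate x age x (32 - GA) x family_sign
  + family coupling x latent factor + Gaussian noise,
  clipped to the legal range of the measure (clipping is logged);
* a scalar standard-normal latent "maturation" factor per subject couples the
  structural families to IQ, working memory, and processing speed;
* clinical raw scores = instrument baseline + age trend + coupling x latent
  factor + noise.

Maturation signs follow the white-matter literature: FA, NDI and volume
increase with age, MD and ODI decrease.  The VPT deviation term opposes the
maturation direction and grows both with age and with the degree of
prematurity, so W-scores computed downstream trend away from zero with age.

The same seed always yields byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .columns import FAMILIES, FAMILY_OF, STRUCTURAL_COLUMNS, X_COLUMNS
from .data_model import ClinicalTable, StructuralTable

logger = logging.getLogger(__name__)

#: Direction of maturation per structural family (+1 increases with age).
FAMILY_SIGN = {"volume": 1.0, "fa": 1.0, "md": -1.0, "ndi": 1.0, "odi": -1.0}

#: Per-measure baselines at the 120-month reference age.  FA/MD/NDI/ODI values
#: follow typical along-tract corpus-callosum profiles (higher FA at genu and
#: splenium); volumes are mm^3 for the five partitions.
MEASURE_BASELINES = {
    "volume_anterior": 880.0,
    "volume_mid_anterior": 450.0,
    "volume_central": 420.0,
    "volume_mid_posterior": 410.0,
    "volume_posterior": 980.0,
    **{f"fa_cc{i}": v for i, v in enumerate((0.66, 0.62, 0.60, 0.58, 0.60, 0.64, 0.70), 1)},
    **{f"md_cc{i}": v for i, v in enumerate((0.92, 0.90, 0.89, 0.90, 0.88, 0.86, 0.84), 1)},
    **{f"ndi_cc{i}": v for i, v in enumerate((0.50, 0.52, 0.53, 0.54, 0.55, 0.56, 0.58), 1)},
    **{f"odi_cc{i}": v for i, v in enumerate((0.14, 0.12, 0.11, 0.10, 0.10, 0.09, 0.08), 1)},
}

#: Legal range per family for clipping, matching the table invariants.
FAMILY_RANGE = {
    "volume": (1e-6, np.inf),
    "fa": (0.0, 1.0),
    "md": (1e-6, np.inf),
    "ndi": (0.0, 1.0),
    "odi": (0.0, 1.0),
}


def _default_age_slopes() -> dict[str, float]:
    # family units per month of age; signs per FAMILY_SIGN
    return {"volume": 1.5, "fa": 5e-4, "md": -5e-4, "ndi": 8e-4, "odi": -2e-4}


def _default_deviation_rate() -> dict[str, float]:
    # family units per (month of age x week of prematurity below 32); sized so
    # the planted deviation trend dominates the gestational-age scatter and
    # bin-norm noise in W-score space at the default cohort size — a stress
    # cohort, deliberately stronger than typical empirical group differences
    return {"volume": 0.3, "fa": 6.0e-4, "md": 4.0e-4, "ndi": 2.5e-4, "odi": 3.0e-4}


def _default_coupling() -> dict[str, float]:
    # loading of the scalar latent maturation factor on clinical instruments
    # (iq points, working-memory items, reaction-time ms) and on the
    # structural families (family units per latent SD, about half a noise SD
    # so the shared factor does not swamp the W-score scale)
    return {
        "iq": 8.0,
        "wm": 1.5,
        "ps": -40.0,
        "volume": 30.0,
        "fa": 0.01,
        "md": -0.015,
        "ndi": 0.015,
        "odi": -0.005,
    }


def _default_noise_sd() -> dict[str, float]:
    return {
        "volume": 60.0,
        "fa": 0.02,
        "md": 0.03,
        "ndi": 0.03,
        "odi": 0.01,
        "iq": 12.0,
        "wm": 2.0,
        "ps": 60.0,
        "inh": 0.05,
        "affect": 2.0,
        "tom": 2.0,
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 39 full-term and 65 very-preterm
    subjects aged 72–173 months, group gestational-age distributions with the
    published means and SDs, and planted clinical–structural associations
    through one scalar latent factor.
    """

    n_ft: int = 39
    n_vpt: int = 65
    age_range_months: tuple[float, float] = (72.0, 173.0)
    ga_ft: tuple[float, float] = (39.83, 1.33)
    ga_vpt: tuple[float, float] = (29.59, 1.73)
    age_slopes: dict[str, float] = field(default_factory=_default_age_slopes)
    vpt_deviation_rate: dict[str, float] = field(default_factory=_default_deviation_rate)
    clinical_coupling: dict[str, float] = field(default_factory=_default_coupling)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    couple_age_ga: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_ft < 8 or self.n_vpt < 8:
            raise ValueError("n_ft and n_vpt must each be >= 8 (4 age bins need filling)")
        lo, hi = self.age_range_months
        if not lo < hi:
            raise ValueError(f"age_range_months {self.age_range_months} is empty")
        if any(s <= 0 for s in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be > 0")


@dataclass
class PlantedTruth:
    """Expected qualitative pattern implied by a :class:`CohortSpec`.

    Signs are +1/-1/0 (0 = no planted effect).  ``clinical_signs`` and
    ``structural_family_signs`` describe the expected loading directions of
    the dominant latent component, up to a global flip of the component.
    ``wscore_age_trend`` / ``wscore_ga_trend`` give the expected sign of the
    OLS slope of VPT W-scores on age and on gestational age.
    """

    clinical_signs: dict[str, int]
    structural_family_signs: dict[str, int]
    wscore_age_trend: dict[str, int]
    wscore_ga_trend: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def planted_truth(spec: CohortSpec) -> PlantedTruth:
    """Ground-truth sign pattern implied by the spec's slopes and couplings."""
    spec.validate()
    coup = spec.clinical_coupling
    dev = spec.vpt_deviation_rate
    slopes = spec.age_slopes

    fam_signs = {}
    for fam in FAMILIES:
        s = 0
        if slopes.get(fam, 0.0) != 0.0 or coup.get(fam, 0.0) != 0.0:
            s = int(FAMILY_SIGN[fam])
        fam_signs[fam] = s

    any_struct_age = any(slopes.get(f, 0.0) != 0.0 for f in FAMILIES)
    clin = {c: 0 for c in X_COLUMNS}
    clin["age_months"] = 1 if any_struct_age else 0
    clin["iq"] = int(np.sign(coup.get("iq", 0.0)))
    clin["wm"] = int(np.sign(coup.get("wm", 0.0)))
    clin["ps"] = int(np.sign(coup.get("ps", 0.0)))

    age_trend = {}
    ga_trend = {}
    for fam in FAMILIES:
        if dev.get(fam, 0.0) > 0:
            # deviation opposes maturation, grows with age, shrinks with GA
            age_trend[fam] = -int(FAMILY_SIGN[fam])
            ga_trend[fam] = int(FAMILY_SIGN[fam])
        else:
            age_trend[fam] = 0
            ga_trend[fam] = 0
    return PlantedTruth(clin, fam_signs, age_trend, ga_trend)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[ClinicalTable, StructuralTable]:
    """Draw one cohort; identical seeds give byte-identical tables."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ft + spec.n_vpt
    groups = np.array(["FT"] * spec.n_ft + ["VPT"] * spec.n_vpt)
    ids = [f"FT{i + 1:03d}" for i in range(spec.n_ft)] + [
        f"VPT{i + 1:03d}" for i in range(spec.n_vpt)
    ]

    lo, hi = spec.age_range_months
    ages = rng.uniform(lo, hi, size=n)
    ga = np.empty(n)
    ga[: spec.n_ft] = _truncnorm(rng, *spec.ga_ft, 37.0, 42.0, spec.n_ft)
    ga[spec.n_ft:] = _truncnorm(rng, *spec.ga_vpt, 24.0, 31.99, spec.n_vpt)
    if spec.couple_age_ga:
        # older participants slightly more preterm (negative age-GA correlation)
        shift = np.where(groups == "VPT", -6.0 * (ga - spec.ga_vpt[0]), 0.0)
        ages = np.clip(ages + shift, lo, hi)
    sex = rng.choice(["F", "M"], size=n)
    latent = rng.standard_normal(n)

    coup = spec.clinical_coupling
    nz = spec.noise_sd
    dev = spec.vpt_deviation_rate
    is_vpt = (groups == "VPT").astype(float)
    prematurity = np.clip(32.0 - ga, 0.0, None) * is_vpt

    struct = {"subject_id": ids}
    n_clipped = 0
    for col in STRUCTURAL_COLUMNS:
        fam = FAMILY_OF[col]
        vals = (
            MEASURE_BASELINES[col]
            + spec.age_slopes.get(fam, 0.0) * (ages - 120.0)
            - dev.get(fam, 0.0) * ages * prematurity * FAMILY_SIGN[fam]
            + coup.get(fam, 0.0) * latent
            + rng.normal(0.0, nz[fam], size=n)
        )
        rlo, rhi = FAMILY_RANGE[fam]
        clipped = np.clip(vals, rlo, rhi)
        n_clipped += int(np.sum(clipped != vals))
        struct[col] = clipped
    if n_clipped:
        logger.warning("generate_cohort: clipped %d structural value(s) to range", n_clipped)

    # clinical raw scores; integer-valued instruments are rounded
    iq = np.clip(100.0 + coup.get("iq", 0.0) * latent + rng.normal(0, nz["iq"], n), 40, 160)
    wm = np.round(
        3.0 + 0.06 * ages + coup.get("wm", 0.0) * latent + rng.normal(0, nz["wm"], n)
    ).clip(0)
    ps = np.clip(
        900.0 - 2.0 * ages + coup.get("ps", 0.0) * latent + rng.normal(0, nz["ps"], n),
        150.0,
        None,
    )
    inh = np.clip(-0.08 + 3e-4 * ages + rng.normal(0, nz["inh"], n), -1.0, 1.0)
    affect = np.round(15.0 + 0.05 * ages + rng.normal(0, nz["affect"], n)).clip(0)
    tom = np.round(12.0 + 0.04 * ages + rng.normal(0, nz["tom"], n)).clip(0)
    bw_mean = np.where(groups == "VPT", 1288.0, 3438.72)
    bw_sd = np.where(groups == "VPT", 378.62, 412.05)
    bw = np.clip(rng.normal(bw_mean, bw_sd), 400.0, None).round(0)
    ses_mean = np.where(groups == "VPT", 4.44, 2.89)
    ses_sd = np.where(groups == "VPT", 2.55, 1.29)
    ses = np.clip(np.round(rng.normal(ses_mean, ses_sd)), 0, 12)

    # column order matches the canonical serialization (required, then optional)
    clin = {
        "subject_id": ids,
        "group": groups,
        "sex": sex,
        "age_months": ages,
        "ga_weeks": ga,
        "iq": iq,
        "wm_raw": wm,
        "ps_raw": ps,
        "inh_raw": inh,
        "affect_raw": affect,
        "tom_raw": tom,
        "birth_weight_g": bw,
        "ses": ses,
    }
    import pandas as pd

    return ClinicalTable(pd.DataFrame(clin)), StructuralTable(pd.DataFrame(struct))
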