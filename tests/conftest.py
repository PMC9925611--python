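import numpy as np
import pandas as pd
import pytest

from cctool.columns import STRUCTURAL_COLUMNS
from cctool.data_model import ClinicalTable, StructuralTable
from cctool.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (39 FT + 65 VPT), fixed seed."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def ft_matrices(default_cohort):
    from cctool.preprocess import build_matrices

    clinical, structural = default_cohort
    return build_matrices(clinical, structural, group="FT")


def make_tiny_cohort(n: int = 3) -> tuple[ClinicalTable, StructuralTable]:
    """Small hand-built valid cohort for I/O and validation tests."""
    rng = np.random.default_rng(99)
    ids = [f"S{i}" for i in range(n)]
    clin = pd.DataFrame({
        "subject_id": ids,
        "group": ["FT", "VPT", "VPT"][:n],
        "sex": ["F", "M", "F"][:n],
        "age_months": [80.0, 120.5, 160.0][:n],
        "ga_weeks": [39.5, 28.0, 30.5][:n],
        "iq": [105.0, 92.0, 88.0][:n],
        "wm_raw": [12.0, 15.0, 18.0][:n],
        "ps_raw": [760.0, 650.0, 580.0][:n],
        "inh_raw": [-0.05, -0.02, -0.08][:n],
        "affect_raw": [19.0, 21.0, 24.0][:n],
        "tom_raw": [15.0, 17.0, 19.0][:n],
        "birth_weight_g": [3400.0, 1100.0, 1500.0][:n],
        "ses": [2.0, 6.0, 4.0][:n],
    })
    struct = {"subject_id": ids}
    for col in STRUCTURAL_COLUMNS:
        if col.startswith("volume"):
            struct[col] = rng.uniform(300, 1000, n).round(3)
        elif col.startswith("md"):
            struct[col] = rng.uniform(0.8, 1.0, n).round(6)
        else:
            struct[col] = rng.uniform(0.1, 0.8, n).round(6)
    return ClinicalTable(clin), StructuralTable(pd.DataFrame(struct))


@pytest.fixture
def tiny_cohort():
    return make_tiny_cohort()
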