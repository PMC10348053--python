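import numpy as np
import pandas as pd
import pytest

from fritrend.fri_data import CohortDataset, Zone
from fritrend.synthcohort import SyntheticParams, generate_cohort

IDENTITY_CONFUSION = tuple(tuple(float(x) for x in row) for row in np.eye(4))


def noiseless_params(**overrides) -> SyntheticParams:
    """A small cohort with no examiner noise, dropout or opacities."""
    base = dict(
        n_participants=30,
        examiner_confusion=IDENTITY_CONFUSION,
        examiner_drift=0.0,
        dropout_per_wave=0.0,
        opacity_rate=0.0,
        duplicate_exam_fraction=0.0,
        seed=7,
    )
    base.update(overrides)
    return SyntheticParams(**base)


@pytest.fixture(scope="session")
def small_cohort() -> CohortDataset:
    """A realistic but small synthetic cohort (noise, dropout, duplicates)."""
    params = SyntheticParams(n_participants=60, seed=11)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def clean_cohort() -> CohortDataset:
    """No missingness beyond eruption, no examiner noise."""
    return generate_cohort(noiseless_params())


def manual_cohort(rows) -> CohortDataset:
    """Build a cohort from (pid, age, examiner, tooth, zone, fri) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "exam_age", "examiner_id", "tooth", "zone", "fri"],
    )
    df["zone"] = df["zone"].map(lambda z: Zone(z).value)
    df["nonfluoride_opacity"] = False
    df["is_primary"] = True
    return CohortDataset(scores=df, waves=tuple(sorted(df["exam_age"].unique())))
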