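"""Shared fixtures: study-sized synthetic cohorts and small geometry helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ektopo.pipeline import annotate_records, cohort_table
from ektopo.synthetic import CohortConfig, sample_cohort

ACCEPTANCE_N = 200
ACCEPTANCE_SEED = 20170  # shipped default seed


@pytest.fixture(scope="session")
def study_frame() -> pd.DataFrame:
    """Annotated metrics table of the calibrated study cohort.

    Control eyes (single visit) plus DMEK/DSAEK eyes followed at 1/3/6
    months, 200 per group — the cohort size used for the calibrated
    group-level summaries. Shared across tests; treat as read-only.
    """
    cfg = CohortConfig(
        sizes={"control": ACCEPTANCE_N, "DMEK": ACCEPTANCE_N, "DSAEK": ACCEPTANCE_N},
        seed=ACCEPTANCE_SEED,
        timepoints={"DMEK": ("1m", "3m", "6m"), "DSAEK": ("1m", "3m", "6m")},
    )
    records = sample_cohort(cfg)
    annotate_records(records, bscva_model=cfg.bscva_model)
    return cohort_table(records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
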