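import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from multimeta.data import MetaDataset, OutcomeRelation, RelationKind


def make_tables(rows):
    return pd.DataFrame(
        rows, columns=["study_id", "outcome_id", "events_t", "n_t",
                       "events_c", "n_c"])


@pytest.fixture
def exclusive_dataset():
    """Four studies, two mutually exclusive outcomes, complete reporting."""
    rows = []
    counts = [
        (30, 20, 100, 25, 25, 100),
        (40, 15, 120, 35, 20, 120),
        (22, 30, 90, 28, 24, 90),
        (55, 40, 200, 60, 35, 200),
    ]
    for i, (a1, a2, nt, c1, c2, nc) in enumerate(counts):
        rows.append((f"s{i+1}", "caesarean", a1, nt, c1, nc))
        rows.append((f"s{i+1}", "instrumental", a2, nt, c2, nc))
    return MetaDataset(
        tables=make_tables(rows),
        relations=[OutcomeRelation("caesarean", "instrumental",
                                   RelationKind.MUTUALLY_EXCLUSIVE)])


@pytest.fixture
def subset_dataset():
    """Five studies; 'death' is a subset of 'death_or_morbidity'."""
    rows = []
    counts = [
        (8, 20, 150, 10, 24, 150),
        (5, 12, 100, 9, 15, 100),
        (12, 25, 220, 14, 26, 220),
        (7, 7, 120, 9, 9, 118),     # subset counts equal superset counts
        (10, 18, 160, 12, 21, 160),
    ]
    for i, (s_t, p_t, nt, s_c, p_c, nc) in enumerate(counts):
        rows.append((f"s{i+1}", "death", s_t, nt, s_c, nc))
        rows.append((f"s{i+1}", "death_or_morbidity", p_t, nt, p_c, nc))
    return MetaDataset(
        tables=make_tables(rows),
        relations=[OutcomeRelation("death", "death_or_morbidity",
                                   RelationKind.SUBSET_A_OF_B)])
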