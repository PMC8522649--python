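import numpy as np
import pandas as pd
import pytest

from mstrans.morphometry import FEATURE_NAMES, SubjectFeatureTable


def make_table(
    n_subjects=8,
    n_regions=12,
    seed=0,
    n_batches=1,
    group_shift=0.0,
    batch_shift=0.0,
    shifted_feature=None,
):
    """Small hand-rolled cohort for unit tests (independent of simulate)."""
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(n_subjects, n_regions, len(FEATURE_NAMES)))
    group = np.array(
        ["case", "control"] * (n_subjects // 2)
        + ["case"] * (n_subjects % 2)
    )
    # block batch assignment, so batch is not confounded with group
    batch = np.array(
        [f"b{(i * n_batches) // n_subjects}" for i in range(n_subjects)]
    )
    if group_shift:
        feats[group == "case"] += group_shift
    if batch_shift:
        sel = batch == "b1"
        if shifted_feature is None:
            feats[sel] += batch_shift
        else:
            feats[sel, :, shifted_feature] += batch_shift
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{i:02d}" for i in range(n_subjects)],
            "group": group,
            "age": rng.normal(70, 5, n_subjects),
            "sex": rng.choice(["M", "F"], n_subjects),
            "education": rng.normal(15, 2, n_subjects),
            "batch": batch,
            "memory_score": rng.normal(0, 1, n_subjects),
        }
    )
    return SubjectFeatureTable(
        features=feats,
        meta=meta,
        region_ids=np.array([f"r{i:02d}" for i in range(n_regions)]),
    )


@pytest.fixture
def small_table():
    return make_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
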