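import numpy as np
import pandas as pd
import pytest

from gliograde.grade_classifier import aggregate_patient_features
from gliograde.pipeline import patch_feature_table
from gliograde.synthetic_cohort import CohortConfig, generate_cohort

#: Patch side used throughout the tests: large enough for tens of nuclei,
#: small enough that a whole cohort is generated and featurized in seconds.
TEST_PATCH_SIZE = 96


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort with the default LGG/HGG contrasts."""
    cfg = CohortConfig(n_patients=30, hgg_fraction=0.5, patches_per_patient=4,
                       patch_size=TEST_PATCH_SIZE, seed=7)
    patches, clinical = generate_cohort(cfg)
    return cfg, patches, clinical


@pytest.fixture(scope="session")
def cohort_table(small_cohort):
    """Patient-level feature table (26 conv + 18 tex + 2 clin + grade)."""
    _, patches, clinical = small_cohort
    patch_df = patch_feature_table(patches)
    return aggregate_patient_features(patch_df.drop(columns=["patch_id"]), clinical)


@pytest.fixture()
def noise_table():
    """A feature table with pure-noise layers and random labels (null data)."""
    rng = np.random.default_rng(42)
    n = 20
    return pd.DataFrame({
        "conv_a": rng.normal(size=n), "conv_b": rng.normal(size=n),
        "tex_a": rng.normal(size=n), "tex_b": rng.normal(size=n),
        "clin_age": rng.normal(50, 10, size=n), "clin_gender": rng.integers(0, 2, n).astype(float),
        "grade": rng.permutation(["HGG"] * (n // 2) + ["LGG"] * (n // 2)),
    })
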