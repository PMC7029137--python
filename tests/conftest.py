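import numpy as np
import pandas as pd
import pytest

from adenomet.data_model import FeatureTable, MetaboliteAnnotation, SampleMetadata
from adenomet.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Reduced cohort used by most integration tests (fast but non-trivial)."""
    return SyntheticConfig(
        n_control=40, n_adenoma=40, n_carcinoma=14,
        n_metabolites=200, n_subpathways=16, n_superpathways=5,
        n_genera=40, n_otus=120, effect_metabolites=10,
        n_perturbed_subpathways=3, sex_effect_metabolites=6,
        effect_size_log10=0.45, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (102/102/36) shared across tests that need it."""
    return generate_cohort(SyntheticConfig(seed=5))


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    rng = np.random.default_rng(0)
    n = 24
    return SampleMetadata(pd.DataFrame({
        "group": ["control", "adenoma"] * (n // 2),
        "age_stratum": rng.choice(["50-59", "60-69", ">=70"], n),
        "sex": ["female", "male", "male", "female"] * (n // 4),
        "race": ["white"] * n,
        "smoking": rng.choice(["smoker", "nonsmoker"], n),
    }, index=[f"s{i}" for i in range(n)]))


def make_table(values, sample_ids=None, feature_ids=None, detected=None,
               tag="raw") -> FeatureTable:
    values = np.asarray(values, float)
    n, m = values.shape
    return FeatureTable(
        values=values,
        detected=np.ones_like(values, bool) if detected is None else detected,
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        feature_ids=feature_ids or [f"f{j}" for j in range(m)],
        scale_tag=tag,
    )


def make_annotation(feature_ids, superpathways, subpathways, known=None
                    ) -> MetaboliteAnnotation:
    known = [True] * len(feature_ids) if known is None else known
    return MetaboliteAnnotation(pd.DataFrame({
        "identity_known": known,
        "superpathway": superpathways,
        "subpathway": subpathways,
    }, index=feature_ids))
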