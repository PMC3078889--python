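import numpy as np
import pytest

from temporalpop.coalescent import IMModelParams, default_study_scheme
from temporalpop.synthetic import StudyDesign, generate_study_like_dataset


@pytest.fixture(scope="session")
def study_scheme():
    return default_study_scheme()


@pytest.fixture(scope="session")
def study_mode_params():
    """An isolation-with-migration parameter vector at the study's inferred
    posterior modes — a convenient, strongly structured truth for synthetic
    datasets."""
    return IMModelParams(
        two_Nm=9.55,
        n_cr_now=271.0,
        ratio_old_now=61.7,
        n_ancestral=2547.0,
        n_western=22376.0,
        t_divergence=891.0,
        t_bottleneck=16.0,
        t_migration=21.0,
        mu=4e-4,
    )


@pytest.fixture(scope="session")
def synthetic_table(study_mode_params):
    """A study-shaped diploid genotype table (14/71/92 individuals, 8 loci)."""
    table, annotations = generate_study_like_dataset(
        study_mode_params, StudyDesign(), seed=2024
    )
    return table, annotations
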