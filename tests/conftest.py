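import warnings

import numpy as np
import pytest

from intraconn.metrics import MetricSettings
from intraconn.synthetic import (CohortConfig, SurfaceMesh, generate_cohort,
                                 generate_region_mesh, generate_streamlines)

warnings.filterwarnings("ignore", message=".*feasible swap.*")


@pytest.fixture(scope="session")
def small_mesh():
    """Four-region sphere with ~400 triangles at the 50k-equivalent density."""
    return generate_region_mesh(4, 400, seed=1)


@pytest.fixture(scope="session")
def mesh16():
    """Default-resolution 16-region mesh (12k-equivalent density)."""
    return generate_region_mesh(16, 1920, seed=2, mean_triangle_area=12.6)


@pytest.fixture(scope="session")
def small_streamlines(small_mesh):
    return generate_streamlines(small_mesh, 800, 0.7, (10.0, 300.0), seed=3)


def tiny_cohort_config(**overrides):
    """A miniature cohort (10 controls, 8 patients) for fast pipeline tests."""
    defaults = dict(
        n_controls=10, control_sex_mf=(5, 5),
        left_sex_mf=(2, 2), right_sex_mf=(2, 2),
        left_outcome_good_bad=(3, 1), right_outcome_good_bad=(2, 2),
        n_regions=4, triangles_per_region=80,
        n_duration_regions=2, n_outcome_regions=1,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    subjects, truth = generate_cohort(tiny_cohort_config(), seed=7)
    return subjects, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-condition cohort (36 controls, 33 patients)."""
    subjects, truth = generate_cohort(CohortConfig(), seed=11)
    return subjects, truth


@pytest.fixture(scope="session")
def fast_settings():
    return MetricSettings(n_nulls=10, seed=0)
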