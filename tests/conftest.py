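import numpy as np
import pytest

from vlsm.imaging import LesionCohort, LesionVolume, TemplateSpace


def make_cohort(per_subject_values, shape=(5, 5, 5), mask=None):
    """Cohort from per-subject 3D arrays (or per-subject scalars broadcast)."""
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    space = TemplateSpace(grid_shape=shape, brain_mask=mask)
    subjects = []
    for i, values in enumerate(per_subject_values):
        data = np.broadcast_to(np.asarray(values, dtype=float), shape).copy()
        subjects.append(LesionVolume(subject_id=f"s{i:02d}", data=data))
    return LesionCohort(subjects=tuple(subjects), space=space)


def make_random_cohort(n_subjects, shape=(5, 5, 5), seed=0, mask=None):
    """Cohort of uniform-random probability volumes (no structure)."""
    rng = np.random.default_rng(seed)
    return make_cohort(
        [rng.random(shape) for _ in range(n_subjects)], shape=shape, mask=mask
    )


@pytest.fixture
def small_space():
    return TemplateSpace(grid_shape=(5, 5, 5), brain_mask=np.ones((5, 5, 5), bool))
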