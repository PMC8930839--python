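import numpy as np
import pytest

from gwfcc import PipelineConfig, SynthConfig, generate_cohort
from gwfcc.synth import analysis_safe_voxels


@pytest.fixture(scope="session")
def fast_synth_config():
    """Small cohort for unit tests: 5+5 subjects, 60 timepoints."""
    return SynthConfig(n_per_group=5, n_timepoints=60, seed=11)


@pytest.fixture(scope="session")
def fast_cohort(fast_synth_config):
    return generate_cohort(fast_synth_config)


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig(seed=11, synth={"n_per_group": 5, "n_timepoints": 60})


@pytest.fixture(scope="session")
def safe_voxels():
    return analysis_safe_voxels((12, 12, 12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_record(bold, probs=None, motion=None, subject_id="S01", group="HC"):
    """Construct a SubjectRecord around a given 4D array."""
    from gwfcc.synth import SubjectRecord

    grid = bold.shape[:3]
    if probs is None:
        probs = {
            "GM": np.full(grid, 0.8),
            "WM": np.full(grid, 0.1),
            "CSF": np.full(grid, 0.1),
        }
    if motion is None:
        motion = np.zeros((bold.shape[3], 6))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        bold=bold,
        affine=np.diag([4.0, 4.0, 4.0, 1.0]),
        tissue_probs=probs,
        motion=motion,
    )
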