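import numpy as np
import pytest

from madvox import SubjectScan, default_spec, generate_cohort


def make_scan(series, subject_id="s0", group="G1", run_id="r1", affine=None):
    """Scan whose single-voxel grid carries the given time series."""
    data = np.asarray(series, dtype=float).reshape(1, 1, 1, -1)
    return SubjectScan(
        data=data,
        affine=np.eye(4) if affine is None else affine,
        tr_seconds=2.0,
        subject_id=subject_id,
        group=group,
        run_id=run_id,
    )


def make_volume_scan(data, subject_id="s0", group="G1", run_id="r1", affine=None):
    return SubjectScan(
        data=np.asarray(data, dtype=float),
        affine=np.eye(4) if affine is None else affine,
        tr_seconds=2.0,
        subject_id=subject_id,
        group=group,
        run_id=run_id,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default recovery cohort (12^3 grid, 140 t, 6+6 subjects, 2 runs)."""
    return generate_cohort(default_spec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
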