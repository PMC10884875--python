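import numpy as np
import pytest

from fcreliab import BoldRun, SyntheticSpec, build_ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale dataset description: 3 subjects, 30 parcels, 3 networks."""
    return SyntheticSpec(
        n_subjects=3,
        n_sessions=4,
        n_parcels=30,
        n_networks=3,
        frames_per_run={"rest": 200, "motor": 150},
        runs_per_state={"rest": 1, "motor": 1},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_gt(small_spec):
    return build_ground_truth(small_spec)


def make_run(data, tr=2.2, subject="sub-01", session=1, run=1, state="rest", mask=None):
    return BoldRun(
        data=np.asarray(data, dtype=float),
        tr_seconds=tr,
        subject=subject,
        session=session,
        run=run,
        state=state,
        censor_mask=mask,
    )
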