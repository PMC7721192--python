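import numpy as np
import pytest

from tagmove import (
    MovementConfig,
    MovementParams,
    ReportingRates,
    StudyFrame,
    TruthSpec,
)


@pytest.fixture
def small_frame() -> StudyFrame:
    """3 regions x 3 years x 4 ages x 1 length class."""
    return StudyFrame(
        years=(2001, 2002, 2003),
        regions=("A", "B", "C"),
        n_ages=4,
        length_classes=("ALL",),
    )


@pytest.fixture
def small_truth(small_frame) -> TruthSpec:
    gamma = np.array([
        [2.0, 0.6, 0.4],
        [0.5, 2.5, 1.0],
        [0.3, 1.2, 1.5],
    ])
    return TruthSpec(
        frame=small_frame,
        movement_config=MovementConfig("C"),
        movement=MovementParams(gamma=gamma),
        M=0.5,
        F=np.full((3, 3), 0.4),
        eta=(2.0, 1.5, 3.5, 1.0),
        lam=np.full((3, 3), 0.5),
        kappa=np.array([[0.4, 0.3, 0.2, 0.1]]),
        releases=np.array(
            [[[3000], [3000], [0]],
             [[3000], [3000], [0]],
             [[3000], [3000], [0]]]
        ),
        age_sample_size=np.array([500]),
    )


@pytest.fixture
def reporting_half(small_frame) -> ReportingRates:
    return ReportingRates(frame=small_frame, lam=np.full((3, 3), 0.5))
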