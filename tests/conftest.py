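import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dltclassify.evaluate import ConfusionMatrix
from dltclassify.synth import TypeGenConfig, generate_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# The published 5x5 agreement table between the final algorithm and the
# expert (expert type in rows, algorithmic type in columns).
REPORTED_MATRIX = np.array(
    [
        [38, 10, 10, 9, 0],
        [1, 43, 22, 23, 0],
        [7, 18, 98, 16, 0],
        [0, 1, 4, 233, 7],
        [0, 0, 0, 9, 51],
    ]
)

STUDY_MIXTURE = (67, 89, 139, 245, 60)


@pytest.fixture(scope="session")
def reported_matrix() -> ConfusionMatrix:
    return ConfusionMatrix(REPORTED_MATRIX.copy())


@pytest.fixture(scope="session")
def small_noise_free():
    """Region-enforced synthetic dataset at a reduced mixture."""
    cfg = TypeGenConfig.default(mixture={1: 12, 2: 15, 3: 23, 4: 41, 5: 10})
    return generate_dataset(cfg, seed=7)
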