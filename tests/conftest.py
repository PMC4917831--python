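import numpy as np
import pytest

from parafundus import (
    BlobParams,
    StreakParams,
    extract_green_channel,
    generate_blob_roi,
    generate_streak_roi,
)


@pytest.fixture(scope="session")
def flame_roi() -> np.ndarray:
    """Green-channel ROI of a strongly oriented streak texture."""
    return extract_green_channel(generate_streak_roi(StreakParams(), seed=11))


@pytest.fixture(scope="session")
def blot_roi() -> np.ndarray:
    """Green-channel ROI of an isotropic dot/blot texture."""
    return extract_green_channel(generate_blob_roi(BlobParams(), seed=11))
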