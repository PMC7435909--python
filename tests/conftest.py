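import numpy as np
import pytest

from gazelabel import SceneSpec, SceneTruth, generate_scene


@pytest.fixture(scope="session")
def default_scene() -> SceneTruth:
    """One seeded default scene shared by read-only tests."""
    return generate_scene(SceneSpec(seed=42))


@pytest.fixture()
def flat_scene() -> SceneTruth:
    """A minimal hand-built scene: one apple center on a black frame."""
    image = np.zeros((200, 300, 3), dtype=np.uint8)
    mask = np.zeros((200, 300), dtype=bool)
    return SceneTruth(
        image=image,
        gt_mask=mask,
        apple_centroids=[(100.0, 100.0)],
        apple_radii=[10.0],
        spec=SceneSpec(width=300, height=200, n_apples=1, sky_band_height=0),
    )
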