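import numpy as np
import pytest

from glossjnd.render import Light, SceneSpec, WardMaterial, render_scene
from glossjnd.synthetic_data import (ALPHA_PAIR, PAPER_MATERIAL_RHO_D,
                                     PAPER_MATERIAL_RHO_S)


@pytest.fixture(scope="session")
def study_material():
    """The study's fixed reflectance at the low (glossy) roughness level."""
    return WardMaterial(PAPER_MATERIAL_RHO_S, PAPER_MATERIAL_RHO_D, ALPHA_PAIR[0])


@pytest.fixture(scope="session")
def point_light_sphere(study_material):
    """Glossy sphere under one point light (full render + mask)."""
    scene = SceneSpec(
        "sphere",
        (Light("point", (40.0, 40.0, 40.0), position=(2.0, -1.0, 3.0)),),
        (45.0, 30.0, 3.0),
        study_material,
        image_size=96,
    )
    return scene, render_scene(scene, "full")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
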