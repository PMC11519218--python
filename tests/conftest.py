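import numpy as np
import pytest
import trimesh

from tibiafit import (
    SubjectProfile,
    TibiaModel,
    default_config,
    footprint_library,
    generate_tibia,
    sample_cohort,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def library(config):
    return footprint_library(config.fitting)


@pytest.fixture(scope="session")
def records(config):
    return sample_cohort(12, config.calibration, seed=1)


@pytest.fixture(scope="session")
def tibia_model(config, records):
    rec = records[0]
    return generate_tibia(rec.profile, rec.target_area, config.anatomy, rec.seed)


@pytest.fixture(scope="session")
def female_profile():
    return SubjectProfile(
        subject_id="F000", sex="female", age=54.0, height=165.0, weight=63.7, bmi=23.4
    )


def make_cylinder(radius: float, height: float = 60.0, sections: int = 360) -> TibiaModel:
    """Right circular cylinder posed as a TibiaModel for analytic slice tests.

    The 'apex' sits on the axis at the cylinder base so a resection plane
    with a given proximal offset cuts through the body.
    """
    mesh = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    mesh.apply_translation([0.0, 0.0, height / 2.0])  # base at z = 0
    return TibiaModel(
        mesh=mesh,
        apex=np.array([0.0, 0.0, 0.0]),
        shaft_axis=np.array([0.0, 0.0, 1.0]),
        anterior_dir=np.array([0.0, 1.0, 0.0]),
        malleolus_margin_points=np.array(
            [[radius, 0.0, 10.0], [radius, 1.0, 20.0], [radius, -1.0, 30.0]]
        ),
        true_area=np.pi * radius**2,
        subject_id=f"cyl-r{radius:g}",
    )
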