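"""Shared fixtures: phantom geometry, a trained shape model, and a case.

Heavy artifacts (population, shape model, carved cases) are session-scoped;
unit tests that only need geometry use coarse voxel pitches to stay fast.
"""

import numpy as np
import pytest
import trimesh
from hypothesis import settings

import acetrec.synthetic_anatomy as syn
from acetrec.shape_model import build_shape_model

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

POPULATION_SEED = 7


@pytest.fixture(scope="session")
def default_params():
    return syn.PhantomParams()


@pytest.fixture(scope="session")
def phantom(default_params):
    """Defect-free default phantom (shared, never mutated)."""
    return syn.make_phantom(default_params, seed=0)


@pytest.fixture(scope="session")
def population():
    """57-member corresponded training population."""
    meshes, params = syn.sample_population(57, seed=POPULATION_SEED)
    return meshes, params


@pytest.fixture(scope="session")
def ssm_model(population):
    meshes, _ = population
    return build_shape_model(meshes)


@pytest.fixture(scope="session")
def medium_case():
    """One posed subject with a carved medium defect (coarse truth grid)."""
    return syn.make_subject("medium", seed=3, pitch=1.0)


@pytest.fixture(scope="session")
def medium_reconstruction(ssm_model, medium_case):
    """Full reconstruction of the medium case at 2-degree ray spacing."""
    import warnings

    from acetrec.defect_reconstruction import reconstruct_defect

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reconstruct_defect(medium_case.pathological_mesh, ssm_model,
                                  angular_spacing=2.0)


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
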