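"""Shared fixtures: synthetic templates, populations and fitted models.

Session-scoped because template construction and model building are pure
functions of fixed seeds; sharing them keeps the suite fast without any
coupling between tests.
"""

import numpy as np
import pytest

from ssmrec.shape_model import build_model
from ssmrec.synthetic import PopulationSpec, generate_population, make_template

POP_SEED = 11


@pytest.fixture(scope="session")
def template_small():
    """Coarse template (642 vertices) for fast registration tests."""
    return make_template(subdivisions=2)


@pytest.fixture(scope="session")
def template():
    """Standard-resolution template (2562 vertices)."""
    return make_template(subdivisions=3)


@pytest.fixture(scope="session")
def population_small(template_small):
    return generate_population(
        template_small.mesh, PopulationSpec(n_shapes=40, seed=POP_SEED)
    )


@pytest.fixture(scope="session")
def model_small(template_small, population_small):
    return build_model(
        population_small.as_corresponded(), n_components=15, template=template_small.mesh
    )


@pytest.fixture(scope="session")
def population(template):
    return generate_population(template.mesh, PopulationSpec(n_shapes=40, seed=POP_SEED))


@pytest.fixture(scope="session")
def model(template, population):
    return build_model(population.as_corresponded(), n_components=15, template=template.mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
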