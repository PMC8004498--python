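"""Shared fixtures: named models and seeded random-model suites."""

from fractions import Fraction

import numpy as np
import pytest

from migrec import (
    MetaPopulation,
    MigrationModel,
    Model,
    PopulationMeasure,
    RandomModelSpec,
    RecombinationDistribution,
    TypeSpace,
    fixture_sojourn_nonmonotone,
    generate_random_model,
)
from migrec.partitions import Partition, bottom, top


@pytest.fixture(scope="session")
def nonmono_cfg():
    """Four sites, one deme; sojourn probabilities 2/5 -> 1/4 -> 1/2 along
    a refinement path (exact rationals)."""
    return fixture_sojourn_nonmonotone()


@pytest.fixture(scope="session")
def nonmono_two_deme_model():
    """The same recombination distribution over two demes with a symmetric
    primitive migration matrix; used for labelled quasi-limiting checks."""
    base = fixture_sojourn_nonmonotone().model
    migration = MigrationModel(["a", "b"], [[0.75, 0.25], [0.25, 0.75]])
    return Model(base.space, base.recombination, migration)


@pytest.fixture(scope="session")
def small_cfg():
    """Three binary sites, two demes; the workhorse random fixture."""
    return generate_random_model(RandomModelSpec(seed=7, n=3, n_demes=2))


@pytest.fixture(scope="session")
def two_site_cfg():
    """Two sites, two demes; support {all-singleton, one-block}."""
    return generate_random_model(
        RandomModelSpec(seed=3, n=2, n_demes=2, support_size=2)
    )


@pytest.fixture(scope="session")
def model_suite():
    """25 seeded random models spanning n in 2..4 and 1..2 demes."""
    cfgs = []
    for i in range(25):
        cfgs.append(
            generate_random_model(
                RandomModelSpec(
                    seed=100 + i,
                    n=2 + i % 3,
                    n_demes=1 + i % 2,
                    support_size=2 + i % 3,
                )
            )
        )
    return cfgs


@pytest.fixture(scope="session")
def ct_cfg():
    return generate_random_model(
        RandomModelSpec(seed=11, n=3, n_demes=2, mode="continuous")
    )


@pytest.fixture(scope="session")
def ct_two_site_cfg():
    return generate_random_model(
        RandomModelSpec(seed=5, n=2, n_demes=2, support_size=2, mode="continuous")
    )


def exact_two_site_model(r0: Fraction, backward) -> Model:
    """Two binary sites with exact r (mass r0 on the split) and given M."""
    space = TypeSpace([["0", "1"], ["0", "1"]])
    g = space.sites
    r = RecombinationDistribution(
        g, {bottom(g): Fraction(r0), top(g): 1 - Fraction(r0)}
    )
    demes = [f"d{i}" for i in range(len(backward))]
    return Model(space, r, MigrationModel(demes, backward))


def dirichlet_metapopulation(model: Model, seed: int) -> MetaPopulation:
    rng = np.random.default_rng(seed)
    meas = []
    for _ in model.demes:
        tab = rng.dirichlet(np.ones(model.space.size()))
        meas.append(
            PopulationMeasure(model.space, model.ground, tab.reshape(model.space.shape()))
        )
    return MetaPopulation(model.demes, meas)
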