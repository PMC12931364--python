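import numpy as np
import pandas as pd
import pytest

from traitscape import (
    CommunityMatrix,
    FunctionSpec,
    ThresholdSet,
    TraitTable,
)
from traitscape.synthetic_fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Default synthetic study system (172 species, 59+19 sites)."""
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture
def toy_pool():
    """Four hand-built species over one binary and one continuous trait."""
    traits = pd.DataFrame(
        {"fire": [1.0, 0.0, 1.0, 0.0], "height": [10.0, 20.0, 30.0, 40.0]},
        index=pd.Index(["a", "b", "c", "d"], name="species_id"),
    )
    return TraitTable(
        traits=traits,
        trait_kind={"fire": "binary", "height": "continuous"},
        provenance=pd.Series(
            ["planted", "planted", "regenerated", "reference_only"],
            index=traits.index,
        ),
    )


@pytest.fixture
def toy_matrix():
    """Three sites over the toy pool; one reference site."""
    ab = pd.DataFrame(
        {"a": [4.0, 0.0, 1.0], "b": [4.0, 2.0, 1.0],
         "c": [0.0, 2.0, 1.0], "d": [0.0, 0.0, 1.0]},
        index=pd.Index(["s1", "s2", "s3"], name="site_id"),
    )
    roles = pd.Series(["restoration", "restoration", "reference"],
                      index=ab.index, name="role")
    return CommunityMatrix(abundances=ab, roles=roles)


@pytest.fixture
def toy_specs():
    return [
        FunctionSpec("fire_fn", "fire", "weighted_mean"),
        FunctionSpec("structure_fn", "height", "weighted_variance"),
    ]


@pytest.fixture
def toy_thresholds():
    return ThresholdSet(
        values={"fire_fn": 0.5, "structure_fn": 50.0},
        directions={"fire_fn": "at_or_above", "structure_fn": "at_or_above"},
    )
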