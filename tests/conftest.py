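import numpy as np
import pytest

import chemcascade as cc


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by read-only tests."""
    config = cc.SimulationConfig(seed=11, n_analog_drugs=8, n_distractor_drugs=8)
    return cc.simulate_study(config)


@pytest.fixture(scope="session")
def library():
    return cc.build_compound_library(cc.SimulationConfig(seed=3))


@pytest.fixture
def benzene():
    return cc.standardize_structure("c1ccccc1", "benzene")


@pytest.fixture
def phenol():
    return cc.standardize_structure("Oc1ccccc1", "phenol")


def make_cell_record(
    compound_id="c1",
    scope_id="PC-3",
    standard_type="IC50",
    relation="=",
    value=500.0,
    units="nM",
):
    return cc.BioactivityRecord(
        compound_id=compound_id,
        activity_scope="cell",
        scope_id=scope_id,
        standard_type=standard_type,
        standard_relation=relation,
        standard_value=value,
        standard_units=units,
        assay_type="F",
        target_type="Cell-line",
        target_organism="Homo Sapiens",
    )


def make_target_record(
    compound_id="c1",
    scope_id="T1",
    standard_type="Ki",
    relation="=",
    value=50.0,
    units="nM",
    target_type="Single protein",
    organism="Homo Sapiens",
    assay="B",
):
    return cc.BioactivityRecord(
        compound_id=compound_id,
        activity_scope="target",
        scope_id=scope_id,
        standard_type=standard_type,
        standard_relation=relation,
        standard_value=value,
        standard_units=units,
        assay_type=assay,
        target_type=target_type,
        target_organism=organism,
    )


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return cc.Transform(rotation=rot, translation=rng.uniform(-5, 5, 3))
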