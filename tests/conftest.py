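import warnings

import pytest

import smsleak as sl


@pytest.fixture(scope="session")
def paper_geom() -> sl.AcquisitionGeometry:
    """The reference protocol: 96x96x68, 2 mm voxels, MB4, GRAPPA 2."""
    return sl.default_geometry()


@pytest.fixture(scope="session")
def reduced_leak_run():
    """One seeded desk-scale run with injected leakage, plus control masks.

    Session-scoped: several tests interrogate the same ground-truth run
    (ranking of alias vs control regions, variance-map peaks).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the anterior alias disk clips the FOV edge
        result = sl.simulate(sl.reduced_scenario(seed=0))
    controls = sl.control_masks(
        result.geom,
        result.alias_locations,
        result.brain_mask,
        n=2,
        min_distance=8,
        seed=0,
    )
    return result, controls
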