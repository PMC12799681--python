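import numpy as np
import pytest

from recepvar import ParcellationAtlas, RegionInfo, build_default_atlas


@pytest.fixture(scope="session")
def default_atlas():
    return build_default_atlas()


@pytest.fixture
def three_region_atlas():
    """Tiny atlas: two cortical regions + one subcortical, 8x8x8 grid."""
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[:3] = 1
    labels[3:5] = 2
    labels[5:] = 3
    regions = [
        RegionInfo(1, "Ctx_L_A_1", "cortex", "L"),
        RegionInfo(2, "Ctx_R_A_1", "cortex", "R"),
        RegionInfo(3, "Sub_L_HIP_1", "subcortex", "L"),
    ]
    return ParcellationAtlas(regions=regions, label_volume=labels)


def tabular_atlas(n, compartment="cortex"):
    """Atlas with no voxel geometry, for pure regional-map statistics."""
    regions = [
        RegionInfo(i + 1, f"R{i + 1}", compartment, "L" if i % 2 == 0 else "R")
        for i in range(n)
    ]
    return ParcellationAtlas(regions=regions, name=f"tabular-{n}")


@pytest.fixture
def atlas20():
    return tabular_atlas(20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
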