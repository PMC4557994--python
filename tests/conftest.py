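import numpy as np
import pytest

from conndiff.atlas import RegionAtlas


@pytest.fixture
def tiny_atlas() -> RegionAtlas:
    """Six regions in three lobe clusters, both hemispheres."""
    return RegionAtlas(
        region_ids=("FroL", "FroR", "TempL", "TempR", "OccL", "OccR"),
        names=tuple(f"region {i}" for i in range(6)),
        hemispheres=("L", "R", "L", "R", "L", "R"),
        clusters=("Fro", "Fro", "Temp", "Temp", "Occ", "Occ"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150902)
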