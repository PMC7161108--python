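import numpy as np
import pytest

from pathme.mapping import FeatureGeneMap, OmicsBlock, PathwayDefinition


@pytest.fixture
def two_modality_blocks():
    """Two tiny omics blocks with partially overlapping patients."""
    rng = np.random.default_rng(42)
    b1 = OmicsBlock("mrna", ["A", "B", "C"], ["G1", "G2", "G3"],
                    rng.normal(size=(3, 3)))
    b2 = OmicsBlock("cnv", ["B", "C", "D"], ["G1", "G3", "G4"],
                    rng.normal(size=(3, 3)))
    return [b1, b2]


@pytest.fixture
def identity_maps(two_modality_blocks):
    return [FeatureGeneMap(b.modality_name, [(f, f) for f in b.features])
            for b in two_modality_blocks]


@pytest.fixture
def small_pathways():
    return [
        PathwayDefinition("PW1", {"G1", "G2", "G3"}),
        PathwayDefinition("PW2", {"G4"}),
        PathwayDefinition("PW3", {"GX"}),  # matches nothing
    ]


@pytest.fixture
def rank1_view_data():
    """Rank-1 structured single-modality data: 20 patients x 6 features."""
    rng = np.random.default_rng(7)
    u = rng.normal(size=20)
    v = rng.normal(size=6)
    return np.outer(u, v) + 0.05 * rng.normal(size=(20, 6))
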