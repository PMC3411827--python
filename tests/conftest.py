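import numpy as np
import pandas as pd
import pytest

from outwelling.community import CommunityMatrix, TraitMatrix
from outwelling.isotopes import IsotopeSignature, SourceEndmember, SourceSet


@pytest.fixture
def spom_sources():
    """Two SPOM endmembers after trophic correction (d13C only informative)."""
    return SourceSet(
        "toy",
        (
            SourceEndmember("estuary-SPOM", IsotopeSignature(-22.5, 5.7)),
            SourceEndmember("marine-SPOM", IsotopeSignature(-19.2, 6.6)),
        ),
    )


@pytest.fixture
def three_sources():
    """Well-separated triangle of corrected sources."""
    return SourceSet(
        "tri",
        (
            SourceEndmember("a", IsotopeSignature(-24.0, 4.0)),
            SourceEndmember("b", IsotopeSignature(-16.0, 6.0)),
            SourceEndmember("c", IsotopeSignature(-20.0, 12.0)),
        ),
    )


@pytest.fixture
def toy_incidence():
    """m=4 samples, S_obs=4, Q1=2, Q2=1 (one empty sample allowed)."""
    counts = pd.DataFrame(
        [
            [1, 0, 2, 1],
            [0, 3, 1, 1],
            [0, 0, 0, 1],
            [0, 0, 0, 0],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C", "D"],
    )
    return CommunityMatrix(counts)


@pytest.fixture
def small_community():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 6, size=(10, 8)),
        index=[f"core{i}" for i in range(10)],
        columns=[f"tax{j}" for j in range(8)],
    )
    counts.iloc[:, 0] += 1  # keep every sample non-empty
    meta = pd.DataFrame(
        {
            "site_id": [f"S{i // 2}" for i in range(10)],
            "location": ["L1"] * 6 + ["L2"] * 4,
        },
        index=counts.index,
    )
    return CommunityMatrix(counts, meta)


@pytest.fixture
def identity_traits(small_community):
    taxa = list(small_community.counts.columns)
    scores = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    return TraitMatrix(scores)
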