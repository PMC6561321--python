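import numpy as np
import pandas as pd
import pytest

from tmtquant.design import CHANNELS, default_design
from tmtquant.ingest import ProteinIntensityMatrix


@pytest.fixture
def design():
    return default_design("plex1")


def make_matrix(values, plex_id="plex1", tech_replicate="rep1", proteins=None):
    """Build a ProteinIntensityMatrix from an array-like of shape (n, 6)."""
    values = np.asarray(values, dtype=float)
    if proteins is None:
        proteins = [f"P{i:04d}" for i in range(1, len(values) + 1)]
    data = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                        columns=list(CHANNELS))
    return ProteinIntensityMatrix(
        plex_id=plex_id,
        tech_replicate=tech_replicate,
        design=default_design(plex_id),
        data=data,
    )


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(np.exp(rng.normal(10, 1, size=(40, 6))))
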