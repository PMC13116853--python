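import numpy as np
import pytest

from wireworm.data import Dataset, PairedObservation, Species


def make_pairs(soil, trap, field_ids=None, species=Species.A_brevis):
    """Build complete-case pairs from parallel count lists."""
    if field_ids is None:
        field_ids = ["F1"] * len(soil)
    return [
        PairedObservation(
            site_id=f, field_id=f, point_id=f"P{i}", species=species,
            soil_count=s, trap_count=t,
        )
        for i, (s, t, f) in enumerate(zip(soil, trap, field_ids))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    obs = make_pairs([0, 0, 1, 3], [0, 2, 0, 4])
    return Dataset(obs, provenance="test fixture")
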