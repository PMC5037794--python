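import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from silkconform import pipeline, structure, synth


@pytest.fixture(scope="session")
def shift_table():
    table, _, _ = pipeline.load_fixtures()
    return table


@pytest.fixture(scope="session")
def inventory():
    _, inv, _ = pipeline.load_fixtures()
    return inv


@pytest.fixture(scope="session")
def six_restraints():
    return pipeline.load_restraints()


@pytest.fixture(scope="session")
def silkI_scaffold():
    return structure.silk_crystal_scaffold("silkI*")


@pytest.fixture(scope="session")
def candidate_model(silkI_scaffold):
    """One seeded candidate complex with 8 glycerols in the default shell."""
    return synth.synth_complex_candidates(
        silkI_scaffold,
        synth.GlycPlacementParams(n_candidates=1, n_glyc_per_model=8,
                                  seed=11))[0]


@pytest.fixture
def film29_fractions():
    """Self-consistent 29 wt % film composition (rc, silk I*, βA, βB)."""
    return (0.526, 0.299, 0.105, 0.070)


@pytest.fixture
def film0_fractions():
    """Glycerol-free film composition: no silk I* mass, β split 0.6/0.4."""
    return (0.616, 0.0, 0.230, 0.154)
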