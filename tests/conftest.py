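import numpy as np
import pytest

from gopharm import FixtureSpec, canonical_orientation, random_molecule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mol():
    """10-atom canonical-frame molecule, compact enough for grid work."""
    spec = FixtureSpec(n_atoms=10, spatial_extent=5.0)
    return canonical_orientation(random_molecule(spec, rng=42, mol_id="small"))


@pytest.fixture
def drug_like_mol():
    """Default 20-atom fixture in the canonical frame."""
    return canonical_orientation(random_molecule(rng=7, mol_id="druglike"))
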