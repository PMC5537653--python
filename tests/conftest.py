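import numpy as np
import pytest

from viromenet.io_formats import ProteinRecord
from viromenet.synthetic_data import FamilySpec, SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_family_config():
    """Two tight families over four phages plus unrelated decoys."""
    return SynthConfig(
        seed=7,
        families=(
            FamilySpec("famA", ("P1", "P2", "P3"), ancestor_length=180,
                       target_identity=90.0, product_label="holin"),
            FamilySpec("famB", ("P1", "P2", "P3", "P4"), ancestor_length=160,
                       target_identity=90.0, product_label="endolysin"),
        ),
        n_singletons=3,
    )


@pytest.fixture
def small_dataset(small_family_config):
    return generate_dataset(small_family_config)


def make_protein(pid, seq, phage="P1", product="hypothetical protein"):
    return ProteinRecord(protein_id=pid, phage_id=phage, product=product, sequence=seq)
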