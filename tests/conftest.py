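import pandas as pd
import pytest

from tfiihkit import synthetic as syn


@pytest.fixture(scope="session")
def inventory() -> pd.DataFrame:
    return syn.default_peptide_inventory()


@pytest.fixture
def noisefree_model() -> syn.ComplexPoolModel:
    return syn.ComplexPoolModel(noise_sigma=0.0)


def make_records(rows):
    """Build an intensity-record frame from (genotype, protein, pep, charge, inj, val)."""
    return pd.DataFrame(
        rows,
        columns=["genotype", "protein_id", "peptide_sequence", "charge_state",
                 "injection", "intensity"],
    )
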