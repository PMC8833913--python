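from importlib import resources

import pytest

from ubinom import StudyConfig, generate_study, read_fasta


@pytest.fixture(scope="session")
def site_fixture_proteome():
    """Packaged stand-in TGFBI/NFKB2 sequences used for site mapping."""
    path = resources.files("ubinom").joinpath("data/synthetic_tgfbi_nfkb2.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study, shared across tests (seed 1)."""
    return generate_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast study for structural checks."""
    return generate_study(
        StudyConfig(n_proteins=60, n_true_substrates=8, n_hif_targets=8,
                    n_patients=60, seed=3)
    )
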