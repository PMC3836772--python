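import pytest

from maxasa import scan, survey

SCAN_SEED = 1


@pytest.fixture(scope="session")
def gly_grid():
    """Full 5-degree scan of Gly-Gly-Gly (shared across tests)."""
    return scan.scan_amino_acid("G", step=5.0, rng_seed=SCAN_SEED)


@pytest.fixture(scope="session")
def ala_grid():
    """Full 5-degree scan of Gly-Ala-Gly."""
    return scan.scan_amino_acid("A", step=5.0, rng_seed=SCAN_SEED)


@pytest.fixture(scope="session")
def ser_grid():
    """Full 5-degree scan of Gly-Ser-Gly with all three chi1 sectors."""
    return scan.scan_amino_acid("S", step=5.0, rng_seed=SCAN_SEED)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Synthetic PDB corpus with planted defects plus its ground truth."""
    root = tmp_path_factory.mktemp("corpus")
    truth = survey.generate_corpus(
        root, n_structures=3, n_residues=50, seed=11,
        occupancy_defects=2, bond_outliers=1)
    return root, truth


@pytest.fixture(scope="session")
def observations(corpus):
    root, _ = corpus
    return survey.collect_observations(root)
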