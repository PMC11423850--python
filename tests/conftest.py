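import pytest

from quatbind.fixtures import FixtureSpec, make_structure_fixture

ACCESSION_DIR_NAME = "data/pdb"


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("structures")


def _make(fixture_dir, kind, seed=1, **params):
    return make_structure_fixture(FixtureSpec(kind, seed=seed, params=params), fixture_dir)


@pytest.fixture(scope="session")
def monomer_fixture(fixture_dir):
    return _make(fixture_dir, "protein_monomer", length=50)


@pytest.fixture(scope="session")
def dimer_fixture(fixture_dir):
    return _make(fixture_dir, "protein_dimer_via_operator", length=100)


@pytest.fixture(scope="session")
def hetero_fixture(fixture_dir):
    return _make(fixture_dir, "hetero_oligomer", length=60, n_chains=2)


@pytest.fixture(scope="session")
def duplex_fixture(fixture_dir):
    return _make(fixture_dir, "bdna_duplex", n_bp=8)


@pytest.fixture(scope="session")
def hairpin_fixture(fixture_dir):
    return _make(fixture_dir, "rna_hairpin_plus_dinucleotide")


@pytest.fixture(scope="session")
def ion_fixture(fixture_dir):
    return _make(fixture_dir, "ion_in_pocket", length=30)


@pytest.fixture(scope="session")
def giant_fixture(fixture_dir):
    return _make(fixture_dir, "many_chain_giant", n_chains=100)


def accession_path(pdb_id):
    """Local mmCIF for a PDB accession; tests red when the file is absent.

    The worked-example accessions cannot be fetched in this offline
    environment; drop ``<pdb_id>.cif`` into data/pdb/ to enable them.
    """
    from pathlib import Path

    root = Path(__file__).resolve().parent.parent
    path = root / ACCESSION_DIR_NAME / f"{pdb_id.lower()}.cif"
    if not path.exists():
        pytest.fail(
            f"accession fixture {path} is unavailable: this environment has no "
            f"network access to fetch PDB {pdb_id.upper()}; place the mmCIF at "
            f"{ACCESSION_DIR_NAME}/{pdb_id.lower()}.cif to run this check"
        )
    return path
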