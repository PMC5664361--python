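import json
from importlib import resources

import pytest

from phyloprof import core_io
from phyloprof.simulate import fixture_small


@pytest.fixture(scope="session")
def bundle():
    """The deterministic in-repo micro-dataset."""
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_expected():
    """Frozen brute-force oracle values for the micro-dataset."""
    with resources.files("phyloprof.data").joinpath("fixture_expected.json").open() as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def bundle_paths(bundle, tmp_path_factory):
    """The micro-dataset written as TSV files."""
    out = tmp_path_factory.mktemp("fixture_small")
    return bundle.write(out)


@pytest.fixture(scope="session")
def loaded(bundle_paths):
    """The micro-dataset round-tripped through every reader."""
    species = core_io.read_species_table(bundle_paths["species"])
    genes, hierarchy = core_io.read_annotation_table(bundle_paths["annotation"], species)
    edges = core_io.read_homology_table(bundle_paths["homology"])
    return {"species": species, "genes": genes, "hierarchy": hierarchy, "edges": edges}


@pytest.fixture()
def species4():
    return core_io.SpeciesSet(("A", "B", "C", "D"), (True, True, True, False))
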