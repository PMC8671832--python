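import math

import pytest

import tadsv
import tadsv.io as tio
from tadsv import fixtures
from tadsv.overlap import group_by_db
from tadsv.pipeline import Resources
from tadsv.regions import TADMap

# canonical term ids of the toy ontology
ROOT = fixtures.ROOT
A1, A2, B1, B2 = fixtures.A1, fixtures.A2, fixtures.B1, fixtures.B2
TERM_A, TERM_B = fixtures.TERM_A, fixtures.TERM_B
D1, D2, D3, D4 = "OMIM:100100", "OMIM:200200", "OMIM:300300", "OMIM:400400"

LN2, LN4, LN43 = math.log(2), math.log(4), math.log(4 / 3)


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy_genome")
    fixtures.make_toy_genome(d, seed=7)
    return d


@pytest.fixture(scope="session")
def manifest(toy_dir):
    import json

    return json.loads((toy_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def resources(toy_dir, manifest):
    files = manifest["files"]
    return Resources(
        tads=TADMap(tio.read_tads(files["tads"], "hESC")),
        genes=tio.read_genes(files["genes"]),
        loops=tio.read_loops(files["loops"], "hESC"),
        clusters=tio.read_clusters(files["clusters"]),
        cytobands=tio.read_cytobands(files["cytobands"]),
        cnv_dbs=group_by_db(tio.read_cnv_db(files["cnv_db"])),
        ontology=tio.read_ontology(files["obo"], files["annotations"]),
    )


@pytest.fixture(scope="session")
def ontology(resources):
    return resources.ontology
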