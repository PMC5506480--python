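import numpy as np
import pytest

from annorbm import GODag, GOTerm

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: branch a
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: branch b
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: leaf a
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000003

[Term]
id: GO:0000005
name: leaf b
namespace: biological_process
is_a: GO:0000003

[Term]
id: GO:0000006
name: dead end
namespace: biological_process
is_obsolete: true
"""

# 10 annotation lines, 2 NOT-qualified, 3 with IEA evidence
TOY_GAF_LINES = [
    ("P1", "", "GO:0000004", "EXP"),
    ("P1", "", "GO:0000005", "IDA"),
    ("P2", "NOT", "GO:0000004", "EXP"),
    ("P2", "", "GO:0000005", "IEA"),
    ("P3", "", "GO:0000002", "EXP"),
    ("P3", "", "GO:0000004", "IEA"),
    ("P4", "NOT|contributes_to", "GO:0000005", "IDA"),
    ("P4", "", "GO:0000003", "TAS"),
    ("P5", "", "GO:0000004", "IEA"),
    ("P5", "", "GO:0000005", "EXP"),
]


def gaf_text(lines=TOY_GAF_LINES):
    rows = ["!gaf-version: 2.1"]
    for prot, qual, term, ev in lines:
        fields = ["TOY", prot, prot, qual, term, "PMID:1", ev, "", "P", "",
                  "", "protein", "taxon:0", "20141027", "TOY", "", ""]
        rows.append("\t".join(fields))
    return "\n".join(rows) + "\n"


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture
def toy_dag(toy_obo):
    from annorbm import parse_obo

    return parse_obo(toy_obo)


@pytest.fixture
def toy_gaf(tmp_path):
    path = tmp_path / "toy.gaf"
    path.write_text(gaf_text())
    return path


def chain_dag(accessions):
    """A linear chain: first accession is the leaf, last is the root."""
    terms = {}
    for i, acc in enumerate(accessions):
        parents = {accessions[i + 1]} if i + 1 < len(accessions) else set()
        terms[acc] = GOTerm(id=acc, parents=parents)
    return GODag(terms)


def random_params(rng, c, m, scale=1.0):
    from annorbm import RBMParams

    return RBMParams(
        rng.normal(0, scale, (c, m)),
        rng.normal(0, scale, c),
        rng.normal(0, scale, m),
    )
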