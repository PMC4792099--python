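import textwrap

import pytest

from pelnet.hpo_ontology import PhenotypeOntology
from pelnet.synthetic_cohort import make_toy_ontology


@pytest.fixture(scope="session")
def toy_ontology() -> PhenotypeOntology:
    """Depth-3, branching-3 tree: 1 + 3 + 9 + 27 = 40 terms."""
    return make_toy_ontology(depth=3, branching=3)


@pytest.fixture
def chain_obo(tmp_path):
    """A 3-term root<-mid<-leaf chain plus one obsolete stanza."""
    path = tmp_path / "chain.obo"
    path.write_text(textwrap.dedent("""\
        format-version: 1.2

        [Term]
        id: HP:0000001
        name: root

        [Term]
        id: HP:0000002
        name: mid
        is_a: HP:0000001 ! root

        [Term]
        id: HP:0000003
        name: leaf
        is_a: HP:0000002 ! mid

        [Term]
        id: HP:0000009
        name: gone
        is_obsolete: true
    """))
    return path


@pytest.fixture
def diamond_ontology() -> PhenotypeOntology:
    """leaf with two parents sharing one grandparent."""
    return PhenotypeOntology.from_parent_map(
        {
            "HP:0000001": [],
            "HP:0000002": ["HP:0000001"],
            "HP:0000003": ["HP:0000001"],
            "HP:0000004": ["HP:0000002", "HP:0000003"],
        }
    )
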