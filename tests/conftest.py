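"""Shared fixtures: a small enzyme lexicon, a mini molecular-function
ontology, and the expanded direction lexicon."""

import io

import pytest

from mutimpact.lexicons import (
    ProteinLexicon,
    build_direction_lexicon,
    load_go,
)

MINI_OBO = """\
format-version: 1.2
ontology: go

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0008270
name: zinc ion binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0018786
name: haloalkane dehalogenase activity
namespace: molecular_function
synonym: "haloalkane halidohydrolase activity" EXACT []
is_a: GO:0003824

[Term]
id: GO:0004089
name: carbonate dehydratase activity
namespace: molecular_function
synonym: "carbonic anhydrase activity" EXACT []
is_a: GO:0003824

[Term]
id: GO:0099999
name: flux capacitance
namespace: biological_process
is_a: GO:0003674
"""


def make_dehalogenase_sequence() -> str:
    """Synthetic 200-residue sequence arranged so that W125F and D170N are
    consistent with author numbering (displacement 0).  A stand-in for a
    real database record, which the test suite does not ship."""
    seq = list("M" + "A" * 199)
    seq[124] = "W"   # 1-based position 125
    seq[169] = "D"   # 1-based position 170
    return "".join(seq)


@pytest.fixture(scope="session")
def dehalogenase_lexicon() -> ProteinLexicon:
    lex = ProteinLexicon()
    lex.add_record(
        "P22643",
        ["Haloalkane dehalogenase"],
        make_dehalogenase_sequence(),
        organisms=["Xanthobacter autotrophicus"],
        go_ids=["GO:0018786"],
        genes=["dhlA"],
    )
    lex.add_record(
        "P22644",
        ["Haloalkane dehalogenase 2"],
        "M" + "G" * 150,
        organisms=["Sphingomonas paucimobilis"],
        go_ids=["GO:0018786"],
        genes=["linB"],
    )
    return lex


@pytest.fixture(scope="session")
def mini_go():
    return load_go(io.StringIO(MINI_OBO))


@pytest.fixture(scope="session")
def dlex():
    return build_direction_lexicon()
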