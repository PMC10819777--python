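"""Shared fixtures: tiny hand-checkable taxonomies and trees."""

import pytest

from taxdiv import parse_taxonomy, read_newick


def dump_line(tax_id, parent_id, rank):
    return f"{tax_id}\t|\t{parent_id}\t|\t{rank}\t|"


@pytest.fixture
def small_taxonomy():
    """root(1) > family(2) > genus(5) > species(10); a second species(11)
    under the same genus; species(12) directly under the family."""
    nodes = "\n".join(
        [
            dump_line(1, 1, "no rank"),
            dump_line(2, 1, "family"),
            dump_line(5, 2, "genus"),
            dump_line(10, 5, "species"),
            dump_line(11, 5, "species"),
            dump_line(12, 2, "species"),
        ]
    )
    return parse_taxonomy(nodes)


@pytest.fixture
def t1():
    """Four-leaf fixture with total branch length 2.1."""
    return read_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6);")


@pytest.fixture
def t2():
    """Grafting fixture: G = {g1, g2, g3} straddles two clades."""
    return read_newick(
        "((g1:0.1,g2:0.1):0.2,((g3:0.1,x1:0.1):0.1,(x2:0.1,x3:0.1):0.1):0.2);"
    )
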