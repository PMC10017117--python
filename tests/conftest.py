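import pathlib

import pytest

import temposcan as ts

TOY_NEWICK = "((A_2000:0.1,B_2001:0.2):0.05,C_2002:0.3);"

# same toy but with root-to-tip distances on a perfect line
# (0.1, 0.2, 0.3 against 2000, 2001, 2002) so the root has signal
PERFECT_NEWICK = "((A_2000:0.05,B_2001:0.15):0.05,C_2002:0.3);"


@pytest.fixture
def toy_tree_path(tmp_path: pathlib.Path) -> pathlib.Path:
    p = tmp_path / "toy.nwk"
    p.write_text(TOY_NEWICK + "\n")
    return p


@pytest.fixture
def toy_tree(toy_tree_path) -> ts.DatedTree:
    return ts.parse_tip_dates(ts.read_tree(toy_tree_path))


@pytest.fixture
def perfect_tree(tmp_path: pathlib.Path) -> ts.DatedTree:
    p = tmp_path / "perfect.nwk"
    p.write_text(PERFECT_NEWICK + "\n")
    return ts.parse_tip_dates(ts.read_tree(p))


def tree_from_newick(tmp_path, newick: str, dated: bool = True) -> ts.DatedTree:
    p = tmp_path / "t.nwk"
    p.write_text(newick + "\n")
    t = ts.read_tree(p)
    return ts.parse_tip_dates(t) if dated else t
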