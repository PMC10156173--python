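from __future__ import annotations

import random

import pytest

from concord import phylo_core as pc


@pytest.fixture
def rng():
    return random.Random(20230901)


@pytest.fixture
def ladder_tree():
    """Canonical concordant backbone: ((g,g),((t,t),(h,h)))."""
    return pc.read_newick("((g1,g2),((t1,t2),(h1,h2)));", rooted=True)


@pytest.fixture
def ladder_clades():
    return {
        "g1": "GLOEO", "g2": "GLOEO",
        "t1": "THERMO", "t2": "THERMO",
        "h1": "HIGHER", "h2": "HIGHER",
    }


def make_alignment(records: dict[str, str]) -> pc.Alignment:
    ids = list(records)
    return pc.Alignment(ids, [records[i] for i in ids])
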