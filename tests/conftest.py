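import json

import numpy as np
import pytest

from ecotree.taxonomy import TaxNode, TaxonomyTree

TOY_RECORDS = [
    {"id": "o_hym", "name": "Hymenoptera", "rank": "order", "parent": None, "role": None},
    {"id": "o_hem", "name": "Hemiptera", "rank": "order", "parent": None, "role": None},
    {"id": "f_bra", "name": "Braconidae", "rank": "family", "parent": "o_hym", "role": None},
    {"id": "f_aph", "name": "Aphididae", "rank": "family", "parent": "o_hem", "role": None},
    {"id": "f_del", "name": "Delphacidae", "rank": "family", "parent": "o_hem", "role": None},
    {"id": "s_tri", "name": "Trichogramma", "rank": "species", "parent": "f_bra", "role": "predator"},
    {"id": "s_cot", "name": "Cotesia glomerata", "rank": "species", "parent": "f_bra", "role": "predator"},
    {"id": "s_gos", "name": "Aphis gossypii", "rank": "species", "parent": "f_aph", "role": "pest"},
    {"id": "s_myz", "name": "Myzus persicae", "rank": "species", "parent": "f_aph", "role": "pest"},
    {"id": "s_nil", "name": "Nilaparvata lugens", "rank": "species", "parent": "f_del", "role": "pest"},
    {"id": "s_lao", "name": "Laodelphax striatellus", "rank": "species", "parent": "f_del", "role": "pest"},
]


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    """2 orders / 3 families / 6 species, including a real parasitoid path."""
    return TaxonomyTree(
        TaxNode(r["id"], r["name"], r["rank"], r["parent"], r["role"]) for r in TOY_RECORDS
    )


@pytest.fixture
def toy_tree_file(tmp_path):
    path = tmp_path / "taxonomy.json"
    path.write_text(json.dumps(TOY_RECORDS))
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
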