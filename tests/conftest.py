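import numpy as np
import pytest

from metaclm.ccr import AnaloguePairTriple, categorize
from metaclm.chem import canonical_smiles, compound_id
from metaclm.curation import CompoundRecord


def make_compound(smiles: str, pki: float) -> CompoundRecord:
    canon = canonical_smiles(smiles)
    return CompoundRecord(compound_id(canon), canon, pki)


def make_triple(sc: str, tc: str, delta: float, sc_pki: float = 5.0,
                core: str = "", class_id: str = "") -> AnaloguePairTriple:
    return AnaloguePairTriple(
        source=make_compound(sc, sc_pki), target=make_compound(tc, sc_pki + delta),
        delta_pot=delta, category=categorize(delta), core=core, class_id=class_id)


@pytest.fixture
def tiny_triples() -> list[AnaloguePairTriple]:
    """Ten small analogue triples for memorisation-scale training runs."""
    pairs = [
        ("Cc1ccccc1", "CCc1ccccc1", 1.0),
        ("Oc1ccccc1", "Nc1ccccc1", 2.5),
        ("Clc1ccccc1", "Brc1ccccc1", -0.5),
        ("CCOc1ccccc1", "COc1ccccc1", 2.0),
        ("CC(C)c1ccccc1", "CCCc1ccccc1", 0.3),
        ("Cc1ccncc1", "CCc1ccncc1", 1.7),
        ("Oc1ccncc1", "Clc1ccncc1", -2.2),
        ("CN(C)c1ccccc1", "CNc1ccccc1", 0.9),
        ("N#Cc1ccccc1", "Cc1ccccc1", 1.4),
        ("FC(F)(F)c1ccccc1", "Fc1ccccc1", -1.1),
    ]
    return [make_triple(a, b, d) for a, b, d in pairs]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
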