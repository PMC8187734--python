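import pytest

from domarchnet.ccs_entities import parse_ccs, classify_entities
from domarchnet.chronology import AgeMap

TOY_LABELS = ["1", "2", "3", "1|2", "3|2", "1|2|3", "4|3|2"]

# distinct ages: domains oldest, containers after their parts
TOY_AGES = {
    "1": 0.0, "2": 0.1, "3": 0.2,
    "1|2": 0.3, "3|2": 0.4, "1|2|3": 0.5, "4|3|2": 0.6,
}


@pytest.fixture(scope="session")
def toy_entities():
    return [parse_ccs(lbl, strict=False) for lbl in TOY_LABELS]


@pytest.fixture(scope="session")
def toy_set(toy_entities):
    return classify_entities(toy_entities)


@pytest.fixture(scope="session")
def toy_ages():
    return AgeMap(dict(TOY_AGES))
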