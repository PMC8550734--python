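import pytest

from spatialcog.relations import parse_assertions, parse_premise


@pytest.fixture
def fruit_premises():
    """The five-fruit worked problem: apricot/pear/fig/kiwi/cherry."""
    return parse_assertions(
        "left;pear;apricot/left;fig;pear/left;kiwi;pear/left;cherry;kiwi"
    )


@pytest.fixture
def city_premises_indeterminate():
    """Opposite cardinal relations: nothing follows for the outer pair."""
    return parse_assertions(
        "south-west;frankfurt;amsterdam/north-east;amsterdam;paris"
    )


@pytest.fixture
def city_premises_determinate():
    """A south-east chain: south-east follows for the outer pair."""
    return parse_assertions(
        "south-east;frankfurt;berlin/south-east;berlin;stockholm"
    )


@pytest.fixture
def apple_premises():
    """The queue-model worked example (apple left of mango and of pear)."""
    return parse_assertions("left;apple;mango/left;apple;pear")
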