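import random

import pytest

from patscan import SequenceRecord, ire_pattern, parse_pattern


@pytest.fixture
def ire_18mer():
    """The canonical eukaryotic IRE: C bulge, GTCAAG stem, CAGTG loop,
    CTTGAC closing stem (DNA spelling)."""
    return SequenceRecord("s1", "", "CGTCAAGCAGTGCTTGAC")


@pytest.fixture
def basic_ire():
    return ire_pattern("basic")


@pytest.fixture
def rng():
    return random.Random(20180502)


def engine_key(match):
    """Hashable view of a match for engine-vs-oracle comparison."""
    return (
        match.start,
        match.end,
        tuple((s.name, s.start, s.end, s.text) for s in match.unit_spans),
    )


@pytest.fixture
def make_pattern():
    return parse_pattern
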