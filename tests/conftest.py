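import pytest

from refcorrect import ContingencyTable, ReferenceAccuracy


@pytest.fixture
def mathews_table() -> ContingencyTable:
    """HRA cytology vs punch biopsy counts."""
    return ContingencyTable(40, 22, 22, 177)


@pytest.fixture
def mathews_ref() -> ReferenceAccuracy:
    return ReferenceAccuracy(0.74, 0.91)


@pytest.fixture
def perfect_ref() -> ReferenceAccuracy:
    return ReferenceAccuracy(1.0, 1.0)
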