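import logging

import pytest

from campusfp.synth import generate_campus_ledger

logging.getLogger("campusfp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """The seed-42 synthetic campus bundle (ledger, factors, damages, drivers)."""
    return generate_campus_ledger(seed=42)


@pytest.fixture()
def tables(bundle):
    return bundle.tables


@pytest.fixture()
def ledger(bundle):
    return bundle.ledger
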