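import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # read-only fixtures are shared across generated inputs on purpose
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("det")

from phosphocov.types import SequenceCatalog, SequenceRecord  # noqa: E402


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def small_catalog():
    """Hand-built catalog exercising review status, taxa and ID maps.

    Lengths are chosen so the one-to-one selection rule has unambiguous
    answers: reviewed P11111 (100) and P22222 (300), unreviewed Q33333
    (500), P44444 (80), P55555 (50); P99999 is mouse; S11111 is a
    secondary alias of P11111; O11111 is obsolete.
    """
    records = {
        "P11111": SequenceRecord("P11111", "M" + "A" * 99, reviewed=True),
        "P22222": SequenceRecord("P22222", "M" + "C" * 299, reviewed=True),
        "Q33333": SequenceRecord("Q33333", "M" + "D" * 499, reviewed=False),
        "P44444": SequenceRecord("P44444", "M" + "E" * 79, reviewed=False),
        "P55555": SequenceRecord("P55555", "M" + "F" * 49, reviewed=False),
        "P99999": SequenceRecord("P99999", "MAAA", taxon=10090),
    }
    return SequenceCatalog(
        records=records,
        secondary_to_primary={"S11111": "P11111"},
        obsolete={"O11111"},
        reference_taxon=9606,
    ).validate()
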