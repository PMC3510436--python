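import random

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return random.Random(20120601)


@pytest.fixture
def small_alignment():
    """Four rows, five columns, one polymorphic column (col 3) and one
    gapped column (col 5 in row d)."""
    from trnapanel.msa import Alignment

    return Alignment(
        row_ids=["a", "b", "c", "d"],
        rows=["ACGTA", "ACGTA", "ACTTA", "ACGT-"],
    )


@pytest.fixture
def synth_trna():
    from trnapanel.synth import SynthParams, make_structured_trna

    params = SynthParams(seed=7)
    rec, ann = make_structured_trna(params)
    return params, rec, ann
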