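import numpy as np
import pytest

from termscan.synthetic import GeneratorParams, make_terminator


@pytest.fixture(scope="session")
def terminator_panel():
    """40 default-parameter annotated terminators (seeded)."""
    rng = np.random.default_rng(7)
    return [
        make_terminator(seed=rng, record_id=f"term_{i}") for i in range(40)
    ]


@pytest.fixture(scope="session")
def fixed_stem_records():
    """Records with an exactly 8-bp stem, for structure-mutation closed forms."""
    params = GeneratorParams(stem_len=(8, 8))
    rng = np.random.default_rng(11)
    return [
        make_terminator(params, seed=rng, record_id=f"s8_{i}") for i in range(30)
    ]
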