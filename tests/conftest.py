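import numpy as np
import pytest

from wrkyscan import SyntheticSpec, make_proteins, make_reference_panel
from wrkyscan.synthetic import GROUPS


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(counts={g: 4 for g in GROUPS})


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """A deterministic small synthetic set: (records, truths, panel)."""
    rng = np.random.default_rng(11)
    records, truths = make_proteins(small_spec, rng)
    panel = make_reference_panel(small_spec, rng)
    return records, truths, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
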