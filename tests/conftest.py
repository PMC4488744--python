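import sys
from pathlib import Path

import numpy as np
import pytest

# make the test oracle importable as a plain module
sys.path.insert(0, str(Path(__file__).parent))

from fragscape.landscape import ALL_LABELS  # noqa: E402


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """One shared seeded three-date demo scenario (generation is the slow part)."""
    from fragscape.pipeline import demo_dataset

    out = tmp_path_factory.mktemp("demo")
    info = demo_dataset(out, seed=1)
    return out, info


def labels_to_names(codes: np.ndarray) -> np.ndarray:
    return np.array(ALL_LABELS, dtype=object)[codes]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
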