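import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from opsinkit.site_annotation import default_frame


@pytest.fixture(scope="session")
def frame():
    return default_frame()


@pytest.fixture(scope="session")
def ref_seq(frame):
    return frame.record.seq
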