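import numpy as np
import pytest

from phenoseq import simulate


@pytest.fixture(scope="session")
def easy_panel():
    return simulate.easy_accession_panel()


@pytest.fixture(scope="session")
def default_panel():
    return simulate.default_accession_panel()


@pytest.fixture(scope="session")
def rosette_frame(easy_panel):
    """One mid-growth rendered frame with its truth mask."""
    return simulate.render_frame(easy_panel[0], day=12, canvas_size=128, seed=7)


@pytest.fixture(scope="session")
def blob_mask():
    """A simple filled-disc mask for descriptor tests."""
    yy, xx = np.mgrid[:96, :96]
    return (yy - 48) ** 2 + (xx - 48) ** 2 <= 30 ** 2
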