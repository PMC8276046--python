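import numpy as np
import pytest

from rootascent.synth import fixture_specs, render_root


@pytest.fixture(scope="session")
def suite():
    """The shipped fixture suite, rendered once per session."""
    rendered = {}
    for name, spec in fixture_specs().items():
        rendered[name] = render_root(spec)
    return rendered


@pytest.fixture
def vertical_band():
    """Width-7 vertical band with its central-column path, rows 10..90."""
    mask = np.zeros((101, 41), bool)
    mask[10:91, 17:24] = True  # cols 17..23, center 20
    path = np.array([(r, 20) for r in range(90, 9, -1)])
    return mask, path
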