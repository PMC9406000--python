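import numpy as np
import pytest

import shiftbind as sb


@pytest.fixture()
def noiseless_two_site():
    """Noiseless two-site titration (Kd 8.7 / 13.5 mM) with its truth."""
    spec = sb.two_site_spec(seed=11, noise_sd_H=0.0, noise_sd_N=0.0)
    tables, truth = sb.simulate_titration(spec)
    return tables, truth


@pytest.fixture()
def noisy_two_site():
    """Two-site titration at default peak-position noise."""
    tables, truth = sb.simulate_titration(sb.two_site_spec(seed=7))
    return tables, truth


@pytest.fixture()
def sparky_fixture(tmp_path):
    """A small hand-written Sparky list on disk."""
    path = tmp_path / "peaks.list"
    path.write_text(
        "      Assignment         w1         w2\n"
        "D99N-H 115.20 8.41\n"
        "E66N-H 120.10 7.95\n"
    )
    return path
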