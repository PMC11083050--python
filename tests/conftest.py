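import numpy as np
import pandas as pd
import pytest

from milletspec import (
    SceneConfig,
    SpectraTable,
    default_wavelength_axis,
    make_signatures,
    render_scan,
)


@pytest.fixture(scope="session")
def axis():
    return default_wavelength_axis()


@pytest.fixture(scope="session")
def signatures(axis):
    return make_signatures(10, axis, separation=0.01, rng_seed=11)


@pytest.fixture(scope="session")
def noise_free_scan(signatures):
    """One rendered scan with zero sensor noise: (raw, white, dark, truth)."""
    return render_scan(signatures[0], SceneConfig(rng_seed=3), noise_sd=0.0)


def make_table(spectra, wavelengths=None, cultivars=None):
    """Assemble a SpectraTable around a plain matrix for unit tests."""
    spectra = np.asarray(spectra, dtype=float)
    n, p = spectra.shape
    if wavelengths is None:
        wavelengths = 900.0 + 3.0 * np.arange(p)
    ann = pd.DataFrame(
        {
            "cultivar": cultivars if cultivars is not None else ["c0"] * n,
            "scan_id": ["s0"] * n,
            "seed_index": np.arange(1, n + 1),
            "pixel_count": np.full(n, 30),
        }
    )
    return SpectraTable(spectra=spectra, wavelengths=np.asarray(wavelengths, float), annotations=ann)


@pytest.fixture()
def table_factory():
    return make_table
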