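import numpy as np
import pytest
from hypothesis import settings

import demar

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return demar.default_library()


@pytest.fixture(scope="session")
def basis_tables(library):
    return library.basis_tables()


@pytest.fixture(scope="session")
def spectra_pair(library):
    """The study's dual-energy spectra (80 and 120 kV, Al+Cu filtered)."""
    filt = [("Al", 2.5), ("Cu", 0.2)]
    return (demar.build_spectrum(80, 9, filt, library),
            demar.build_spectrum(120, 9, filt, library))


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-sized geometry for unit tests (64-pixel grid)."""
    return demar.Geometry(n_views=90, image_size=64)


def make_disc(n, radius_px, value, center=None):
    c = (n - 1) / 2.0 if center is None else center
    rr, cc = np.ogrid[:n, :n]
    img = np.zeros((n, n))
    img[(rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2] = value
    return img
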