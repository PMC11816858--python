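import numpy as np
import pytest

from bnctkit import dosimetry


@pytest.fixture(scope="session")
def rate_tables():
    """Bundled Monte-Carlo dose-rate constants per culture geometry."""
    return dosimetry.load_dose_rate_table()


@pytest.fixture(scope="session")
def spheroid_rates(rate_tables):
    return rate_tables[dosimetry.CultureType.spheroid]


@pytest.fixture(scope="session")
def flask_rates(rate_tables):
    return rate_tables[dosimetry.CultureType.flask2D]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


#: Published planning-table rows for the spheroid cultures:
#: (P kW, C_B ppm, sigma_C_B, D_tot Gy, D_0 Gy)
SPHEROID_PLAN_ROWS = [
    ("WM266-4 3D lower", 17, 36.0, 6.8, 3.14, 0.61),
    ("FM55p 3D lower", 12, 47.5, 4.6, 2.78, 0.43),
    ("WM266-4 3D higher", 51, 36.0, 6.8, 9.33, 1.82),
    ("FM55p 3D higher", 36, 47.5, 4.6, 8.30, 1.28),
]

#: Published thermal fluxes (cm^-2 s^-1) at each reactor power (kW),
#: printed to 3 significant figures.
FLUX_ROWS = [
    (20, 9.60e8),
    (60, 2.88e9),
    (17, 8.16e8),
    (12, 5.76e8),
    (51, 2.45e9),
    (36, 1.73e9),
]
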