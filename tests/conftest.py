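import numpy as np
import pytest
from hypothesis import settings

import nitrauv as nv

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lib():
    return nv.default_library()


@pytest.fixture(scope="session")
def grid():
    # working grid covering the modeling and CDOM windows
    return nv.default_grid(200.0, 280.0, 0.4)


ZERO_SOLUTES = {
    "sodium nitrate": 0.0,
    "sodium humate": 0.0,
    "sodium dihydrogen phosphate": 0.0,
    "sodium nitrite": 0.0,
}

SALT_NAMES = (
    "sodium chloride",
    "magnesium sulfate",
    "sodium bicarbonate",
    "sodium bromide",
)


def pure_nitrate_overrides(conc_mol_per_L):
    """Overrides that zero everything except nitrate."""
    out = {name: 0.0 for name in SALT_NAMES}
    out.update(ZERO_SOLUTES)
    out["sodium nitrate"] = conc_mol_per_L
    return out


@pytest.fixture(scope="session")
def tsc_model(lib, grid):
    cal = nv.generate_lns_calibration(lib, np.arange(4.0, 26.0), grid=grid)
    return nv.fit_tsc(cal)


def make_table(grid, A, T, S, conc=None, prefix="s"):
    A = np.atleast_2d(A)
    n = A.shape[0]
    return nv.SampleTable(
        sample_ids=[f"{prefix}{i}" for i in range(n)],
        wavelengths=grid,
        absorbance=A,
        temperature=np.asarray(T, dtype=float),
        salinity=np.asarray(S, dtype=float),
        reference_conc=None if conc is None else np.asarray(conc, dtype=float),
    )
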