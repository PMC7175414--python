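from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

import oximetric as ox

_hyp_settings.register_profile("ci", derandomize=True)
_hyp_settings.load_profile("ci")
from oximetric.metric import build_reference_line

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table():
    return ox.load_default_table()


@pytest.fixture(scope="session")
def grid():
    return ox.DEFAULT_GRID


@pytest.fixture(scope="session")
def reference_line(table, grid):
    return build_reference_line(table, grid)


@pytest.fixture(scope="session")
def stored_noise_spectra():
    """Ten frozen pure-noise spectra on the default grid (text fixture)."""
    from oximetric.fitting import read_spectra_table

    return read_spectra_table(DATA / "noise_spectra.tsv")


@pytest.fixture(scope="session")
def raw_fixture_rows():
    """The packaged chromophore table parsed independently of the package
    loader, for by-hand lookups."""
    import importlib.resources as r

    rows = {}
    text = r.files("oximetric.data").joinpath("hb_absorption_150gL.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        lam, oxy, deoxy = line.split("\t")
        rows[float(lam)] = (float(oxy), float(deoxy))
    return rows
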