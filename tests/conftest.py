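"""Shared fixtures: small synthetic libraries, runs, and spectra."""

import numpy as np
import pytest

from ms2deconv import MS1Feature, RunData, Spectrum
from ms2deconv.simulate import make_synthetic_library, simulate_dda_run


@pytest.fixture
def simple_spectrum():
    return Spectrum(
        mz=[100.0, 150.0, 200.0], intensity=[50.0, 100.0, 25.0],
        precursor_mz=250.0, precursor_rt=300.0,
    )


@pytest.fixture(scope="session")
def tiny_library(tmp_path_factory):
    """30 random compounds, most with a near-isobaric chimera partner."""
    path = tmp_path_factory.mktemp("lib") / "tiny.sqlite"
    library, manifest = make_synthetic_library(
        path, n_compounds=30, seed=7, chimera_partner_fraction=0.7,
    )
    yield library, manifest
    library.close()


@pytest.fixture(scope="session")
def dda_fixture(tiny_library):
    """One simulated DDA replicate: half the features chimeric."""
    library, manifest = tiny_library
    runs, features, truth = simulate_dda_run(
        library, manifest, n_features=8, chimera_fraction=0.5, seed=7,
    )
    return runs[0], features, truth, library


@pytest.fixture
def two_scan_run():
    """Minimal run: one MS1 scan with two in-window centroids + one MS2."""
    ms1 = Spectrum(
        mz=[200.00, 200.30, 350.0], intensity=[1e6, 5e5, 2e6],
        precursor_rt=100.0, ms_level=1,
    )
    ms2 = Spectrum(
        mz=[80.0, 120.0], intensity=[100.0, 40.0],
        precursor_mz=200.0, precursor_rt=101.0, ms_level=2,
        isolation_low=199.5, isolation_high=200.5,
    )
    return RunData(ms1_scans=[ms1], ms2_scans=[ms2])


@pytest.fixture
def feature_200():
    return MS1Feature(mz_med=200.0, rt_med=100.0, intensity=1e6, feature_id="F1")
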