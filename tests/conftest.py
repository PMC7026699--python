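import warnings

import pytest

from pctpath import fit_calibration, load_catalogue, run_experiment

SLAB_ENERGIES = (210.0, 215.0, 220.0, 225.0, 230.0)


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def calibration(catalogue):
    return fit_calibration(catalogue)


@pytest.fixture(scope="session")
def water_bundle():
    """20 cm water cube, 200 MeV, 3000 tracks, 2-sigma cuts (clean Gaussian)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment("water", n_tracks=3000, seed=11, bootstrap=0)


@pytest.fixture(scope="session")
def slab_bundles():
    """Bone-slab runs at each nominal beam energy, 3000 tracks, 2-sigma cuts."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for e in SLAB_ENERGIES:
            out[e] = run_experiment(
                "slab", n_tracks=3000, seed=int(23 + e), energy=e, bootstrap=0
            )
    return out
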