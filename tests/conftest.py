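"""Shared fixtures: time grids, synthetic AIFs and analyzed phantoms.

Expensive phantom builds and voxelwise fits are session-scoped so the whole
suite pays for them once.
"""

import numpy as np
import pytest

import dce2tcm as d


@pytest.fixture(scope="session")
def times_min():
    """The standard dynamic grid: 60 frames at 8.3 s/frame, minutes."""
    return np.arange(60) * 8.3 / 60.0


@pytest.fixture(scope="session")
def phantom_aif(times_min):
    return d.synthetic_aif(times_min)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless phantom, fully analyzed through the AIF stage."""
    ph = d.build_phantom(d.default_spec(noise_sd=0.0, seed=0))
    t1map = d.fit_vfa_t1(ph.vfa)
    conc = d.signal_to_concentration(ph.dynamic, t1map)
    aif = d.extract_aif(conc, ph.roi_masks["blood"])
    return ph, t1map, conc, aif


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    """Tofts and 2TCM parametric maps of the noiseless phantom."""
    ph, _, conc, aif = noiseless_phantom
    tissue = (ph.region_map > 0) & ~ph.roi_masks["blood"]
    slices = ph.spec.roi_slices
    return {
        "tofts": d.fit_volume(conc, aif, slices, "tofts", mask=tissue),
        "2tcm": d.fit_volume(conc, aif, slices, "2tcm", mask=tissue, seed=0),
    }


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with Gaussian noise at 1% of the normal-tissue baseline signal."""
    spec = d.default_spec(seed=11)
    spec.noise_sd = 0.01 * d.baseline_signal(spec)
    ph = d.build_phantom(spec)
    t1map = d.fit_vfa_t1(ph.vfa)
    conc = d.signal_to_concentration(ph.dynamic, t1map)
    aif = d.extract_aif(conc, ph.roi_masks["blood"])
    return ph, t1map, conc, aif


@pytest.fixture(scope="session")
def noisy_maps(noisy_phantom):
    ph, _, conc, aif = noisy_phantom
    tissue = (ph.region_map > 0) & ~ph.roi_masks["blood"]
    slices = ph.spec.roi_slices
    return {
        "tofts": d.fit_volume(conc, aif, slices, "tofts", mask=tissue),
        "2tcm": d.fit_volume(conc, aif, slices, "2tcm", mask=tissue, seed=0),
    }
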