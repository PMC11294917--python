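import numpy as np
import pytest

from prmquant.msdata import InclusionEntry, ReferenceSpectrum, Run, Spectrum
from prmquant.simulate import AcquisitionConfig, SimTarget


def make_ms1(scan_id, rt, peaks):
    mz = np.array([p[0] for p in peaks], float)
    inten = np.array([p[1] for p in peaks], float)
    return Spectrum(scan_id, 1, rt, mz, inten)


def make_ms2(scan_id, rt, precursor_mz, peaks):
    mz = np.array([p[0] for p in peaks], float)
    inten = np.array([p[1] for p in peaks], float)
    return Spectrum(scan_id, 2, rt, mz, inten, precursor_mz=precursor_mz)


@pytest.fixture
def small_run():
    """1 MS1 + 3 MS2 scans around rt 5 min for precursor 471.2740."""
    spectra = [
        make_ms1("s1", 4.9, [(471.2740, 500.0), (472.2770, 120.0)]),
        make_ms2("s2", 5.0, 471.2740, [(281.19, 10.0), (263.18, 5.0)]),
        make_ms2("s3", 5.1, 471.2740, [(281.19, 100.0), (263.18, 50.0)]),
        make_ms2("s4", 5.2, 471.2740, [(281.19, 10.0), (263.18, 5.0)]),
    ]
    return Run("small", spectra)


@pytest.fixture
def entry_471():
    return InclusionEntry("wfa", 471.2740, 5.0, 1.0)


@pytest.fixture
def ref_wfa():
    return ReferenceSpectrum(
        "wfa", ((281.1900, 1.0), (263.1794, 0.6), (109.0648, 0.3))
    )


def flat_target(
    target_id="flat",
    intensity=1000.0,
    rt_apex=1.0,
    mz_mass=470.2668,
    fragments=((281.19, 1.0), (263.18, 0.5)),
    **kw,
):
    """Target whose chromatographic peak is flat at `intensity` cps over any
    realistic gradient (huge sigma), for scheduler arithmetic tests."""
    return SimTarget(
        target_id,
        mz_mass,
        "M+H",
        rt_apex,
        1e9,
        intensity,
        1.0,
        tuple(fragments),
        **kw,
    )


@pytest.fixture
def short_config():
    return AcquisitionConfig(gradient_length=2.0, noise_cv=0.0, seed=0)
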