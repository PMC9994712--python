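import numpy as np
import pytest

from phascreen import ftir_spectra as fs
from phascreen import synthetic_data as sd

GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / (4 * np.log(2))))


def gaussian_area(height: float, fwhm: float) -> float:
    """Closed-form area of a Gaussian band parameterized by height and FWHM."""
    return height * fwhm * GAUSS_AREA_FACTOR


def chord_corrected_gaussian_area(height: float, fwhm: float, center: float,
                                  lo: float, hi: float) -> float:
    """Analytic oracle for the chord-baselined band integral over [lo, hi].

    Closed-form Gaussian area, minus the two tails outside the region
    (via erf), minus the trapezoid under the chord through the Gaussian's
    endpoint values.  Independent of the trapezoidal integration path.
    """
    from math import erf, exp, log, sqrt
    k = 4 * log(2) / fwhm**2
    sigma = fwhm / (2 * sqrt(2 * log(2)))

    def g(x):
        return height * exp(-k * (x - center) ** 2)

    def cdf(x):
        return 0.5 * (1 + erf((x - center) / (sigma * sqrt(2))))

    total = gaussian_area(height, fwhm)
    inside = total * (cdf(hi) - cdf(lo))
    chord = 0.5 * (g(lo) + g(hi)) * (hi - lo)
    return inside - chord


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Demo fixture written and fully analyzed once per test session."""
    from phascreen import pipeline_cli as pipe

    root = tmp_path_factory.mktemp("demo")
    out = pipe.make_demo_fixture(seed=11, out_dir=root)
    cfg = pipe.load_config(out / "config.yaml")
    report = pipe.run_screening(cfg, out / "results")
    return {"dir": out, "config": cfg, "report": report,
            "results": out / "results"}


@pytest.fixture
def cary():
    return fs.CARY


@pytest.fixture
def hts_xt():
    return fs.HTS_XT


@pytest.fixture
def two_band_spectrum():
    """Noise-free amide I + carbonyl-ester spectrum on the default grid."""
    bands = [sd.BandSpec(1650.0, 0.5, 40.0), sd.BandSpec(1728.0, 0.2, 20.0)]
    return sd.generate_spectrum(bands, sd.SimConfig())
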