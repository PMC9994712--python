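import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phascreen import ftir_spectra as fs
from phascreen import synthetic_data as sd

from conftest import chord_corrected_gaussian_area, gaussian_area


# ---------------------------------------------------------------------------
# I/O

class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, two_band_spectrum):
        path = fs.write_spectrum(two_band_spectrum, tmp_path / "s.csv")
        back = fs.read_spectrum(path)
        assert np.array_equal(back.wavenumbers, two_band_spectrum.wavenumbers)
        assert np.array_equal(back.absorbances, two_band_spectrum.absorbances)

    def test_descending_file_reversed(self, tmp_path, two_band_spectrum):
        path = tmp_path / "desc.csv"
        with open(path, "w") as fh:
            fh.write("wavenumber_cm-1,absorbance\n")
            for nu, a in zip(two_band_spectrum.wavenumbers[::-1],
                             two_band_spectrum.absorbances[::-1]):
                fh.write(f"{float(nu)!r},{float(a)!r}\n")
        back = fs.read_spectrum(path)
        assert np.array_equal(back.wavenumbers, two_band_spectrum.wavenumbers)
        assert np.array_equal(back.absorbances, two_band_spectrum.absorbances)

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        rows = [(1000 + 2 * i, 0.1) for i in range(10)]
        rows.insert(5, rows[4])
        with open(path, "w") as fh:
            fh.write("wavenumber_cm-1,absorbance\n")
            for nu, a in rows:
                fh.write(f"{nu},{a}\n")
        with pytest.raises(fs.SpectrumParseError, match="monotone"):
            fs.read_spectrum(path)

    def test_non_numeric_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        lines = ["wavenumber_cm-1,absorbance"]
        lines += [f"{1000 + i},0.1" for i in range(9)]
        lines[4] = "oops,0.1"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(fs.SpectrumParseError, match="line 5"):
            fs.read_spectrum(path)

    def test_too_few_points(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("wavenumber_cm-1,absorbance\n1000,0.1\n1002,0.2\n")
        with pytest.raises(fs.SpectrumParseError):
            fs.read_spectrum(path)

    def test_jcamp_xydata(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=synthetic\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n"
            "##XFACTOR=1\n##YFACTOR=0.001\n##FIRSTX=1000\n##LASTX=1014\n"
            "##DELTAX=2\n##NPOINTS=8\n##XYDATA=(X++(Y..Y))\n"
            "1000 100 200 300 400\n1008 500 600 700 800\n##END=\n")
        s = fs.read_spectrum(path)
        assert s.wavenumbers[0] == 1000
        assert s.wavenumbers[-1] == 1014
        assert s.absorbances[0] == pytest.approx(0.1)
        assert s.absorbances[-1] == pytest.approx(0.8)


# ---------------------------------------------------------------------------
# Normalization and baseline

class TestNormalize:
    def test_anchor_scaling(self, cary):
        nu = np.linspace(1500, 1800, 151)
        s = fs.Spectrum(nu, np.full(nu.size, 1.25))
        n = fs.normalize_spectrum(s, cary)
        assert n.value_at(1650.0) == pytest.approx(0.5)
        assert np.allclose(n.absorbances, 0.5)

    def test_idempotence(self, cary, two_band_spectrum):
        once = fs.normalize_spectrum(two_band_spectrum, cary)
        twice = fs.normalize_spectrum(once, cary)
        assert np.allclose(once.absorbances, twice.absorbances, atol=1e-15)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        bands = [sd.BandSpec(1650.0, 0.5, 40.0)]
        s = sd.generate_spectrum(bands, sd.SimConfig(baseline_offset=0.05))
        scaled = s.with_absorbances(s.absorbances * c)
        a = fs.normalize_spectrum(s, fs.CARY)
        b = fs.normalize_spectrum(scaled, fs.CARY)
        assert np.allclose(a.absorbances, b.absorbances, atol=1e-12)

    def test_nonpositive_anchor_rejected(self, cary):
        nu = np.linspace(1500, 1800, 151)
        s = fs.Spectrum(nu, np.zeros(nu.size))
        with pytest.raises(ValueError, match="normalize"):
            fs.normalize_spectrum(s, cary)


class TestBaseline:
    def test_affine_becomes_zero(self):
        nu = np.linspace(900, 4000, 1551)
        s = fs.Spectrum(nu, 0.3 + 1e-4 * nu)
        b = fs.baseline_correct_linear(s)
        assert np.allclose(b.absorbances, 0.0, atol=1e-12)

    def test_flat_becomes_zero(self):
        nu = np.linspace(900, 4000, 100)
        b = fs.baseline_correct_linear(fs.Spectrum(nu, np.full(100, 0.1)))
        assert np.allclose(b.absorbances, 0.0)
        assert b.absorbances[0] == 0.0 and b.absorbances[-1] == 0.0

    def test_band_on_affine_baseline(self):
        # residual equals the pure band minus the chord of its endpoint values
        cfg = sd.SimConfig(baseline_offset=0.2, baseline_slope=3e-5)
        s = sd.generate_spectrum([sd.BandSpec(1728.0, 0.2, 20.0)], cfg)
        pure = sd.generate_spectrum([sd.BandSpec(1728.0, 0.2, 20.0)],
                                    sd.SimConfig())
        b = fs.baseline_correct_linear(s)
        chord = np.interp(s.wavenumbers,
                          [s.wavenumbers[0], s.wavenumbers[-1]],
                          [pure.absorbances[0], pure.absorbances[-1]])
        assert np.allclose(b.absorbances, pure.absorbances - chord, atol=1e-10)


# ---------------------------------------------------------------------------
# Band integration

class TestIntegrateBand:
    def test_affine_spectrum_zero_area(self, cary):
        nu = np.linspace(900, 4000, 1551)
        s = fs.Spectrum(nu, 0.05 + 2e-5 * nu)
        assert fs.integrate_band(s, cary.carbonyl_region) == 0.0

    def test_gaussian_chord_tail_oracle(self, cary):
        # the stated example band: refined analytic oracle (chord + erf tails)
        s = sd.generate_spectrum([sd.BandSpec(1728.0, 0.2, 20.0)], sd.SimConfig())
        area = fs.integrate_band(s, cary.carbonyl_region)
        oracle = chord_corrected_gaussian_area(0.2, 20.0, 1728.0, 1705.0, 1763.0)
        assert area == pytest.approx(oracle, rel=0.005)
        # coarse closed-form comparison; chord/tail loss keeps it within 5%
        assert area == pytest.approx(gaussian_area(0.2, 20.0), rel=0.05)

    def test_fully_contained_band_within_2pct(self, cary):
        # band >= 4 sigma from both region edges
        s = sd.generate_spectrum([sd.BandSpec(1734.0, 0.2, 14.0)], sd.SimConfig())
        area = fs.integrate_band(s, cary.carbonyl_region)
        assert area == pytest.approx(gaussian_area(0.2, 14.0), rel=0.02)

    @given(offset=st.floats(-1, 1), slope=st.floats(-1e-3, 1e-3))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, offset, slope):
        s = sd.generate_spectrum([sd.BandSpec(1728.0, 0.2, 20.0)],
                                 sd.SimConfig(seed=1, noise_sd=0.002))
        base = fs.integrate_band(s, fs.CARY.carbonyl_region)
        shifted = s.with_absorbances(s.absorbances + offset + slope * s.wavenumbers)
        assert fs.integrate_band(shifted, fs.CARY.carbonyl_region) == \
            pytest.approx(base, abs=1e-9)

    def test_region_outside_grid_rejected(self, cary):
        nu = np.linspace(1800, 2000, 101)
        s = fs.Spectrum(nu, np.zeros(101))
        with pytest.raises(ValueError, match="outside grid"):
            fs.integrate_band(s, cary.carbonyl_region)

    def test_negative_area_floored(self, cary):
        # concave-down dip below the chord
        nu = np.linspace(1600, 1800, 201)
        dip = -0.3 * np.exp(-((nu - 1730) / 12.0) ** 2)
        s = fs.Spectrum(nu, 0.5 + dip)
        assert fs.integrate_band(s, cary.carbonyl_region) == 0.0


# ---------------------------------------------------------------------------
# Peak finding and classification

class TestFindPeak:
    def test_locates_constructed_band(self, cary):
        s = sd.generate_spectrum([sd.BandSpec(1728.0, 0.2, 20.0)], sd.SimConfig())
        peak = fs.find_carbonyl_peak(s, cary.carbonyl_region)
        assert peak == pytest.approx(1728.0, abs=2.0)

    def test_flat_region_returns_none(self, cary):
        nu = np.linspace(900, 4000, 1551)
        s = fs.Spectrum(nu, np.full(nu.size, 0.1))
        assert fs.find_carbonyl_peak(s, cary.carbonyl_region) is None

    def test_below_prominence_returns_none(self, cary):
        s = sd.generate_spectrum([sd.BandSpec(1728.0, 0.003, 20.0)], sd.SimConfig())
        assert fs.find_carbonyl_peak(s, cary.carbonyl_region,
                                     min_prominence=0.005) is None

    def test_window_larger_than_region_rejected(self, cary):
        s = sd.generate_spectrum([], sd.SimConfig(baseline_offset=0.1))
        with pytest.raises(ValueError, match="smooth_window"):
            fs.find_carbonyl_peak(s, cary.carbonyl_region, smooth_window=999)


class TestClassifyPha:
    @pytest.mark.parametrize("peak,expected", [
        (1728.0, "scl"),   # scl-type carbonyl peak position
        (1738.0, "mcl"),   # mcl-type position
        (1723.0, "scl"),   # ATR-variant scl position
        (None, "none"),
        (1733.0, "scl"),   # boundary inclusive on the scl side
    ])
    def test_classification(self, peak, expected):
        assert fs.classify_pha(peak) == expected

    def test_custom_boundary(self):
        assert fs.classify_pha(1730.0, boundary=1725.0) == "mcl"


# ---------------------------------------------------------------------------
# CA1 pipeline

class TestComputeCA1:
    def test_two_band_ratio(self, cary, two_band_spectrum):
        result = fs.compute_ca1(two_band_spectrum, cary)
        carb = chord_corrected_gaussian_area(0.2, 20.0, 1728.0, 1705.0, 1763.0)
        amide = chord_corrected_gaussian_area(0.5, 40.0, 1650.0, 1580.0, 1705.0)
        assert result.ca1_ratio == pytest.approx(carb / amide, rel=0.03)
        # and within 3.5% of the pure closed-form ratio 0.2 (chord/tail loss)
        assert result.ca1_ratio == pytest.approx(0.2, rel=0.035)
        assert result.pha_class == "scl"

    def test_fully_contained_bands_match_ratio_within_3pct(self, cary):
        bands = [sd.BandSpec(1650.0, 0.5, 30.0), sd.BandSpec(1734.0, 0.2, 14.0)]
        s = sd.generate_spectrum(bands, sd.SimConfig())
        result = fs.compute_ca1(s, cary)
        expected = gaussian_area(0.2, 14.0) / gaussian_area(0.5, 30.0)
        assert result.ca1_ratio == pytest.approx(expected, rel=0.03)

    def test_no_carbonyl_band(self, cary):
        s = sd.generate_spectrum([sd.BandSpec(1650.0, 0.5, 40.0)], sd.SimConfig())
        result = fs.compute_ca1(s, cary)
        assert result.carbonyl_area == pytest.approx(0.0, abs=1e-6)
        assert result.ca1_ratio == pytest.approx(0.0, abs=1e-6)
        assert result.carbonyl_peak is None
        assert result.pha_class == "none"

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        bands = [sd.BandSpec(1650.0, 0.5, 40.0), sd.BandSpec(1728.0, 0.2, 20.0)]
        s = sd.generate_spectrum(bands, sd.SimConfig())
        scaled = s.with_absorbances(s.absorbances * c)
        a = fs.compute_ca1(s, fs.CARY)
        b = fs.compute_ca1(scaled, fs.CARY)
        assert b.ca1_ratio == pytest.approx(a.ca1_ratio, rel=1e-9)
        assert b.carbonyl_peak == a.carbonyl_peak
        assert b.pha_class == a.pha_class

    def test_monotone_in_carbonyl_height(self, cary):
        ratios = []
        for h in (0.05, 0.1, 0.2, 0.4):
            bands = [sd.BandSpec(1650.0, 0.5, 40.0), sd.BandSpec(1728.0, h, 20.0)]
            s = sd.generate_spectrum(bands, sd.SimConfig())
            ratios.append(fs.compute_ca1(s, cary).ca1_ratio)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_result_invariant(self, cary, two_band_spectrum):
        r = fs.compute_ca1(two_band_spectrum, cary)
        assert r.ca1_ratio == pytest.approx(r.carbonyl_area / r.amide1_area)
        assert (r.pha_class == "none") == (r.carbonyl_peak is None)


# ---------------------------------------------------------------------------
# Aggregation

class TestAggregateCA1:
    @staticmethod
    def _result(sample_id, ratio, substrate="glc"):
        return fs.CA1Result(sample_id=sample_id, carbonyl_area=ratio,
                            amide1_area=1.0, ca1_ratio=ratio,
                            carbonyl_peak=1728.0, pha_class="scl",
                            metadata={"substrate": substrate})

    def test_identical_ratios(self):
        results = [self._result(f"s{i}", 0.2) for i in range(3)]
        frame = fs.aggregate_ca1(results)
        assert frame.loc["glc", "mean"] == pytest.approx(0.2)
        assert frame.loc["glc", "sd"] == pytest.approx(0.0)

    def test_hand_quartiles(self):
        results = [self._result(f"s{i}", v) for i, v in enumerate([1, 2, 3, 4])]
        frame = fs.aggregate_ca1(results)
        assert frame.loc["glc", "median"] == pytest.approx(2.5)
        assert frame.loc["glc", "q1"] == pytest.approx(1.75)
        assert frame.loc["glc", "q3"] == pytest.approx(3.25)
        assert frame.loc["glc", "fence_lo"] == pytest.approx(1.75 - 1.5 * 1.5)
        assert frame.loc["glc", "fence_hi"] == pytest.approx(3.25 + 1.5 * 1.5)

    def test_singleton_sd_missing(self):
        frame = fs.aggregate_ca1([self._result("s0", 0.3)])
        assert frame.loc["glc", "mean"] == pytest.approx(0.3)
        assert np.isnan(frame.loc["glc", "sd"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fs.aggregate_ca1([])
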