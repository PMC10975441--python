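"""Contracts of the seven spectral pretreatments."""
import numpy as np
import pytest

from hsimoist import PreprocessSpec, Preprocessor, preprocess
from hsimoist.containers import SpectraMatrix
from hsimoist.errors import ConfigurationError, DegenerateSpectrumError
from hsimoist.preprocessing import METHODS


def sm(values, wl=None):
    values = np.atleast_2d(values)
    wl = np.linspace(1000, 2400, values.shape[1]) if wl is None else np.asarray(wl)
    return SpectraMatrix(values, wl)


@pytest.fixture
def spectra(rng):
    base = np.linspace(0.8, 0.3, 40) + 0.1 * np.sin(np.linspace(0, 7, 40))
    return sm(base + rng.normal(0, 0.02, (6, 40)))


@pytest.mark.parametrize("method", METHODS)
def test_shape_and_wavelengths_preserved(spectra, method):
    out = preprocess(spectra, PreprocessSpec(method=method))
    assert out.values.shape == spectra.values.shape
    assert np.array_equal(out.wavelengths, spectra.wavelengths)


class TestSNV:
    def test_zero_mean_unit_sd(self, spectra):
        out = preprocess(spectra, PreprocessSpec(method="snv"))
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        assert np.abs(out.values.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_idempotent(self, spectra):
        spec = PreprocessSpec(method="snv")
        once = preprocess(spectra, spec)
        twice = preprocess(once, spec)
        assert np.allclose(once.values, twice.values)

    def test_constant_row_raises_with_row_index(self):
        x = sm(np.vstack([np.linspace(0, 1, 10), np.full(10, 0.4)]))
        with pytest.raises(DegenerateSpectrumError) as exc:
            preprocess(x, PreprocessSpec(method="snv"))
        assert exc.value.row == 1


class TestMSC:
    def test_reference_equal_to_spectrum_is_identity(self):
        s = np.linspace(0.2, 0.9, 25) ** 1.5
        x = sm(s)
        out = preprocess(x, PreprocessSpec(method="msc", msc_reference=s))
        assert np.allclose(out.values[0], s, atol=1e-10)

    def test_reference_frozen_from_calibration(self, spectra):
        pre = Preprocessor(PreprocessSpec(method="msc")).fit(spectra)
        assert np.allclose(pre.reference_, spectra.values.mean(axis=0))
        # transforming new data must not change the reference
        other = sm(spectra.values[:2] * 1.3 + 0.05)
        pre.transform(other)
        assert np.allclose(pre.reference_, spectra.values.mean(axis=0))


@pytest.mark.parametrize("method", ["snv", "msc"])
def test_scatter_family_collapses_to_one_point(method, rng):
    # {a + b*s : b > 0} must map to a single corrected spectrum
    s = np.linspace(0.3, 0.8, 30) + 0.15 * np.exp(-0.5 * ((np.arange(30) - 12) / 3.0) ** 2)
    family = np.vstack([a + b * s for a, b in [(0.0, 1.0), (0.1, 0.7), (-0.05, 1.8)]])
    x = sm(family)
    pre = Preprocessor(PreprocessSpec(method=method, msc_reference=s)).fit(x)
    out = pre.transform(x).values
    assert np.abs(out - out[0]).max() < 1e-8


class TestSmoothing:
    def test_moving_average_shrinking_edges(self):
        x = sm([[1.0, 2.0, 3.0, 4.0, 5.0]])
        out = preprocess(x, PreprocessSpec(method="moving_average", window=3))
        assert np.allclose(out.values[0], [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_savgol_interpolating_case_is_identity(self, spectra):
        out = preprocess(
            spectra, PreprocessSpec(method="savitzky_golay", window=7, poly_order=6)
        )
        assert np.allclose(out.values, spectra.values, atol=1e-8)

    def test_savgol_smooths_noise(self, rng):
        clean = np.linspace(0.2, 0.8, 60)
        noisy = sm(clean + rng.normal(0, 0.05, (1, 60)))
        out = preprocess(noisy, PreprocessSpec(method="savitzky_golay"))
        assert np.abs(out.values[0] - clean).mean() < np.abs(noisy.values[0] - clean).mean()


class TestBaselineAndDetrending:
    def test_detrending_annihilates_polynomial(self):
        wl = np.linspace(1000, 2400, 50)
        quad = 0.3 + 0.001 * wl + 2e-7 * wl**2
        out = preprocess(sm(quad, wl), PreprocessSpec(method="detrending", poly_order=2))
        assert np.abs(out.values).max() < 1e-9

    def test_baseline_endpoints_and_min(self, spectra):
        out = preprocess(spectra, PreprocessSpec(method="baseline"))
        assert np.allclose(out.values.min(axis=1), 0.0, atol=1e-12)
        # endpoint line removed: both endpoints now equal (their residual is 0
        # before the min shift, so they differ from 0 only by the min offset)
        assert np.allclose(out.values[:, 0], out.values[:, -1])


class TestNormalization:
    def test_minmax_range_and_idempotence(self, spectra):
        spec = PreprocessSpec(method="normalization")
        out = preprocess(spectra, spec)
        assert np.allclose(out.values.min(axis=1), 0.0)
        assert np.allclose(out.values.max(axis=1), 1.0)
        assert np.allclose(preprocess(out, spec).values, out.values)

    def test_unit_vector_variant(self, spectra):
        out = preprocess(
            spectra, PreprocessSpec(method="normalization", norm_variant="unit_vector")
        )
        assert np.allclose(np.linalg.norm(out.values, axis=1), 1.0)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"method": "nope"},
            {"method": "savitzky_golay", "window": 4},
            {"method": "savitzky_golay", "window": 5, "poly_order": 5},
            {"method": "moving_average", "window": 1},
            {"method": "normalization", "norm_variant": "zscore"},
        ],
    )
    def test_invalid_spec(self, kw):
        with pytest.raises(ConfigurationError):
            Preprocessor(PreprocessSpec(**kw))

    def test_yaml_roundtrip(self, tmp_path):
        spec = PreprocessSpec(method="msc", msc_reference=np.linspace(0, 1, 5))
        spec.to_yaml(tmp_path / "p.yaml")
        back = PreprocessSpec.from_yaml(tmp_path / "p.yaml")
        assert back.method == "msc"
        assert np.allclose(back.msc_reference, spec.msc_reference)
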