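import numpy as np
import pytest

from fireflysim.exceptions import DegenerateFeatureError, DomainError
from fireflysim.features import (AbsorptionFeature, classify_regions,
                                 feature_depth, find_features,
                                 subsampled_depth_loss, track_peak_drift)
from fireflysim.scene import (convolve_to_bands, default_scene_config,
                              make_highres_spectrum)


@pytest.fixture(scope="module")
def band_spectrum(instrument, noisefree_scene):
    """Noise-free full-band irradiance spectrum at the reference pixel,
    from the calibrated default configuration."""
    hr = make_highres_spectrum(noisefree_scene.config)
    return convolve_to_bands(hr, 133, instrument)


class TestFindFeatures:
    def test_monotone_spectrum_is_featureless(self, instrument):
        spec = np.linspace(10.0, 50.0, instrument.grid.n_bands)
        assert find_features(spec, instrument=instrument) == []

    def test_single_dip_pairs_with_highest_window_band(self, instrument):
        spec = np.full(instrument.grid.n_bands, 100.0)
        spec[999] = 50.0        # valley at band 1000
        spec[1002] = 130.0      # highest within +-3 -> peak at band 1003
        feats = find_features(spec, instrument=instrument)
        assert [(f.valley_band, f.peak_band) for f in feats] == [(1000, 1003)]
        assert feats[0].k == pytest.approx(50.0 / 130.0)

    def test_peak_conflict_deeper_valley_wins(self, instrument):
        # both valleys prefer band 1002; the deeper (band 1000) keeps it
        # and the other re-pairs inside its remaining window
        spec = np.full(instrument.grid.n_bands, 100.0)
        spec[999] = 40.0    # valley band 1000, k = 40/130
        spec[1001] = 130.0  # band 1002, best peak for both valleys
        spec[1003] = 50.0   # valley band 1004, k = 50/130 (shallower)
        spec[1004] = 110.0  # band 1005: second-best peak for valley 1004
        feats = {f.valley_band: f for f in
                 find_features(spec, instrument=instrument)}
        assert feats[1000].peak_band == 1002
        assert feats[1004].peak_band == 1005
        assert feats[1004].k == pytest.approx(50.0 / 110.0)

    def test_shape_mismatch(self, instrument):
        with pytest.raises(DomainError, match="n_bands"):
            find_features(np.ones(100), instrument=instrument)

    def test_catalogue_peaks_unique(self, band_spectrum, instrument):
        feats = find_features(band_spectrum, instrument=instrument)
        peaks = [f.peak_band for f in feats]
        assert len(set(peaks)) == len(peaks)
        assert len(feats) > 100

    def test_shallowing_with_wider_fwhm(self, instrument, noisefree_scene):
        # every genuine feature (k < 0.99) gets strictly shallower as the
        # FWHM grows from 0.12 to 0.2 nm; micro-minima on the saturated
        # oxygen trough floors (k ~ 1) are excluded as degenerate
        hr = make_highres_spectrum(noisefree_scene.config)
        narrow = convolve_to_bands(hr, 133, instrument, fwhm_override=0.12)
        wide = convolve_to_bands(hr, 133, instrument, fwhm_override=0.2)
        f_narrow = {f.valley_band: f for f in
                    find_features(narrow, instrument=instrument)}
        f_wide = {f.valley_band: f for f in
                  find_features(wide, instrument=instrument)}
        checked = 0
        for vb, f in f_narrow.items():
            if f.k >= 0.99:
                continue
            match = next((f_wide[b] for b in range(vb - 1, vb + 2)
                          if b in f_wide), None)
            if match is None:
                continue   # feature disappeared entirely: fully shallowed
            assert match.k > f.k, f"feature at band {vb} did not shallow"
            checked += 1
        assert checked > 100


class TestFeatureDepth:
    def test_oxygen_a_worked_values(self):
        # in-flight oxygen-A statistics: valley 16.88, peak 164.94
        spec = np.array([164.94, 30.0, 16.88])
        f = AbsorptionFeature(valley_band=3, peak_band=1, k=0.5)
        assert feature_depth(spec, f) == pytest.approx(0.1023, abs=5e-4)

    def test_simple_ratio(self):
        spec = np.array([100.0, 60.0, 50.0])
        f = AbsorptionFeature(valley_band=3, peak_band=1, k=0.5)
        assert feature_depth(spec, f) == 0.5

    def test_equal_radiance_means_no_feature(self):
        spec = np.array([80.0, 60.0, 80.0])
        f = AbsorptionFeature(valley_band=1, peak_band=3, k=0.5)
        assert feature_depth(spec, f) == 1.0

    def test_nonpositive_peak_rejected(self):
        f = AbsorptionFeature(valley_band=1, peak_band=3, k=0.5)
        with pytest.raises(DegenerateFeatureError):
            feature_depth(np.array([1.0, 1.0, 0.0]), f)

    def test_feature_invariants(self):
        with pytest.raises(DomainError):
            AbsorptionFeature(valley_band=10, peak_band=15, k=0.5)
        with pytest.raises(DegenerateFeatureError):
            AbsorptionFeature(valley_band=10, peak_band=12, k=1.2)


class TestRegions:
    @pytest.mark.parametrize("wavelength,expected", [
        (761.0, {"O2A"}),
        (700.0, {"O2B", "water_vapor", "leaf_slope"}),
        (775.0, {"polynomial_sif"}),
        (757.0, {"split_window"}),
        (759.0, {"O2A"}),            # shared endpoint belongs to O2A
        (770.5, {"O2A"}),
        (680.0, {"water_vapor"}),
    ])
    def test_examples(self, wavelength, expected):
        assert classify_regions(wavelength) == frozenset(expected)

    def test_every_wavelength_tagged(self):
        for w in np.arange(670.0, 781.0, 0.05):
            assert len(classify_regions(float(w))) >= 1


class TestPeakDrift:
    def _features(self, spec, instrument):
        # drift tracking follows prominent features whose summit dominates
        # its +-4-band neighbourhood (slope-pinned peaks cannot drift)
        out = []
        for f in find_features(spec, instrument=instrument):
            if f.k >= 0.8:
                continue
            nom = f.peak_band - 1
            lo, hi = max(0, nom - 3), min(len(spec), nom + 4)
            j = lo + int(np.argmax(spec[lo:hi]))
            ext = spec[max(0, nom - 4):nom + 5]
            if (nom - 3 < j < nom + 3 and spec[j] == ext.max()
                    and (ext == spec[j]).sum() == 1
                    and spec[j] > spec[j - 1] and spec[j] > spec[j + 1]):
                out.append(f)
        return out[:25]

    def test_identical_spectra_zero_offsets(self, band_spectrum, instrument):
        feats = self._features(band_spectrum, instrument)
        table = track_peak_drift([band_spectrum] * 4, feats)
        offs = table[[c for c in table if c.startswith("acq_")]].to_numpy()
        assert np.all(offs == 0)
        assert not table.shift_flag.any()

    def test_one_band_shift_flagged(self, band_spectrum, instrument):
        feats = self._features(band_spectrum, instrument)
        shifted = np.roll(band_spectrum, 1)
        table = track_peak_drift([band_spectrum] * 3 + [shifted] * 2, feats)
        offs = table[[c for c in table if c.startswith("acq_")]].to_numpy()
        # offsets are measured from the modal band: the unshifted majority
        # sits at 0, the shifted acquisitions at a consistent +-1
        assert np.all(offs[:, :3] == 0)
        assert np.all(np.abs(offs[:, 3:]) == 1)
        assert np.all(np.sign(offs[:, 3]) == np.sign(offs[:, 4]))
        assert table.shift_flag.all()

    def test_noise_rarely_moves_peaks(self, band_spectrum, instrument):
        feats = self._features(band_spectrum, instrument)
        rng = np.random.default_rng(7)
        spectra = [band_spectrum
                   + rng.normal(0, band_spectrum / 200.0)  # SNR 200
                   for _ in range(20)]
        table = track_peak_drift(spectra, feats)
        offs = table[[c for c in table if c.startswith("acq_")]].to_numpy()
        assert (np.abs(offs) <= 1).mean() >= 0.95

    def test_needs_two_spectra(self, band_spectrum, instrument):
        feats = self._features(band_spectrum, instrument)
        with pytest.raises(DomainError):
            track_peak_drift([band_spectrum], feats)


class TestSamplingResolution:
    def test_halving_resolution_loses_depth(self, band_spectrum):
        losses = subsampled_depth_loss(band_spectrum)
        assert len(losses) > 50
        # a coarser comb can only miss extrema, so every feature's depth is
        # reduced or preserved, and the mean loss is strictly positive
        assert (losses.loss >= 0.0).all()
        assert losses.loss.mean() > 0.0
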