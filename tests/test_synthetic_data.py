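"""Band library contents and the synthetic spectrum/elemental generator."""

import numpy as np
import pytest

from gypsospec.band_assignment import assign_peaks, detect_peaks, \
    summarise_features
from gypsospec.spectra_io import Group
from gypsospec.synthetic_data import (
    SyntheticConfig,
    default_profiles,
    make_band_library,
    simulate_dataset,
    simulate_spectrum,
)


def local_max_near(spectrum, center, tol):
    """Is there a local maximum within +-tol cm^-1 of center?"""
    wn, ab = spectrum.wavenumbers, spectrum.absorbances
    window = (wn >= center - tol) & (wn <= center + tol)
    idx = np.flatnonzero(window)
    for i in idx:
        if 0 < i < len(ab) - 1 and ab[i] >= ab[i - 1] and ab[i] >= ab[i + 1]:
            return True
    return False


@pytest.fixture(scope="module")
def library():
    return make_band_library()


class TestBandLibrary:
    def test_1615_is_calcium_oxalate(self, library):
        hits = [b for b in library if b.center == 1615]
        assert hits and hits[0].characterisation == "calcium oxalate"

    def test_597_is_gypsum(self, library):
        hits = [b for b in library if b.center == 597]
        assert hits and hits[0].characterisation == "gypsum"

    def test_all_centers_within_acquisition_range(self, library):
        assert all(370 <= b.center <= 4000 for b in library)

    def test_required_bands_present(self, library):
        centers = {b.center for b in library}
        for c in (3522, 3400, 3340, 2920, 2850, 1686, 1653, 1615, 1550,
                  1426, 1371, 1312, 874, 835, 780, 720, 715, 669, 597):
            assert c in centers, f"band {c} missing from library"
        ranges = {b.band_range for b in library if b.band_range}
        assert (1720, 1740) in ranges       # esters
        assert (1707, 1710) in ranges       # carboxylic acids
        assert (1080, 1140) in ranges       # sulphates other than gypsum
        assert (610, 680) in ranges

    def test_range_bands_are_ordered(self, library):
        for b in library:
            if b.band_range:
                assert b.band_range[0] < b.band_range[1]


class TestSimulateSpectrum:
    def test_same_seed_gives_identical_spectra(self):
        cfg = SyntheticConfig(seed=11)
        prof = default_profiles()[Group.WIDE_GYPSOPHILE]
        s1 = simulate_spectrum(prof, cfg, np.random.default_rng(7))
        s2 = simulate_spectrum(prof, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(s1.absorbances, s2.absorbances)

    def test_wide_gypsophile_shows_gypsum_band_maxima(self):
        cfg = SyntheticConfig(seed=2, noise_sd=0.0)
        prof = default_profiles()[Group.WIDE_GYPSOPHILE]
        s = simulate_spectrum(prof, cfg, np.random.default_rng(2))
        for center in (3522, 3400, 669, 597):
            assert local_max_near(s, center, tol=4), \
                f"no local maximum near {center}"

    def test_gypsovag_lacks_gypsum_but_shows_amide(self):
        cfg = SyntheticConfig(seed=2, noise_sd=0.0)
        prof = default_profiles()[Group.GYPSOVAG]
        s = simulate_spectrum(prof, cfg, np.random.default_rng(2))
        assert not local_max_near(s, 597, tol=10)
        assert local_max_near(s, 1653, tol=4)

    def test_empty_grid_is_an_error(self):
        cfg = SyntheticConfig(seed=0, grid=np.array([]))
        prof = default_profiles()[Group.GYPSOVAG]
        with pytest.raises(ValueError, match="empty"):
            simulate_spectrum(prof, cfg, np.random.default_rng(0))


class TestSimulateDataset:
    def test_default_design_has_44_samples(self, default_dataset):
        sset, elems = default_dataset
        assert len(sset) == 44
        assert len(elems) == 44
        counts = {g: sum(1 for s in sset if s.group is g)
                  for g in (Group.GYPSOVAG, Group.NARROW_ENDEMISM,
                            Group.WIDE_GYPSOPHILE)}
        assert counts == {Group.GYPSOVAG: 17, Group.NARROW_ENDEMISM: 12,
                          Group.WIDE_GYPSOPHILE: 15}
        assert sset.sample_ids == elems.sample_ids

    def test_sulphur_exactly_linear_in_sulphate_areas_at_zero_noise(self):
        cfg = SyntheticConfig(seed=4, noise_sd=0.0, element_noise_cv=0.0)
        _, elems = simulate_dataset(cfg)
        areas = elems.band_areas
        predictor = areas["gypsum"] + areas["sulphate_other"]
        s = elems.analyte("S (%)")
        coef = np.polyfit(predictor, s, 1)
        np.testing.assert_allclose(coef[0], cfg.alpha_s, rtol=1e-10)
        np.testing.assert_allclose(coef[1], 0.0, atol=1e-10)
        residual = s - cfg.alpha_s * predictor
        np.testing.assert_allclose(residual, 0.0, atol=1e-12)

    def test_coupling_recovered_by_regression_under_noise(self):
        cfg = SyntheticConfig(seed=8, group_sizes={
            Group.GYPSOVAG: 60, Group.NARROW_ENDEMISM: 60,
            Group.WIDE_GYPSOPHILE: 60})
        _, elems = simulate_dataset(cfg)
        x = (elems.band_areas["gypsum"]
             + elems.band_areas["sulphate_other"]).to_numpy()
        y = elems.analyte("S (%)")
        X = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        n = len(y)
        sigma2 = float(res[0]) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[0, 0])
        assert abs(coef[0] - cfg.alpha_s) < 3 * se

    def test_potassium_is_decoupled_from_the_spectrum(self):
        cfg = SyntheticConfig(seed=9, group_sizes={
            Group.GYPSOVAG: 170, Group.NARROW_ENDEMISM: 160,
            Group.WIDE_GYPSOPHILE: 170})
        sset, elems = simulate_dataset(cfg)
        k = elems.analyte("K (mg/g)")
        matrix = sset.to_matrix()
        # intensity at a gypsum band and at an organic band
        for center in (597.0, 1653.0):
            j = int(np.argmin(np.abs(sset.grid - center)))
            r = np.corrcoef(k, matrix[:, j])[0, 1]
            assert abs(r) < 0.15

    def test_group_identity_recoverable_from_noiseless_bands(
            self, noiseless_dataset):
        sset, _ = noiseless_dataset
        for s in sset:
            flags = summarise_features(assign_peaks(detect_peaks(s)))
            if s.group is Group.WIDE_GYPSOPHILE:
                assert flags.gypsum_present
            else:
                assert not flags.gypsum_present
            if s.group is Group.NARROW_ENDEMISM:
                assert flags.oxalate_present

    def test_too_few_samples_is_an_error(self):
        cfg = SyntheticConfig(group_sizes={Group.GYPSOVAG: 1,
                                           Group.NARROW_ENDEMISM: 0,
                                           Group.WIDE_GYPSOPHILE: 0})
        with pytest.raises(ValueError, match="at least 2"):
            simulate_dataset(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(overlap_fraction=1.5)

    def test_yaml_config_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 42\nnoise_sd: 0.02\noverlap_fraction: 0.1\n")
        cfg = SyntheticConfig.from_yaml(p)
        assert cfg.seed == 42 and cfg.noise_sd == 0.02
        p.write_text("sede: 1\n")
        with pytest.raises(ValueError, match="unknown config"):
            SyntheticConfig.from_yaml(p)
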