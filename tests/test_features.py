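"""Region energies, data-driven region selection, and featurization."""

import numpy as np
import pytest

from ftirseed.dwt import WaveletSpec, coeff_to_wavenumber, dwt_multilevel
from ftirseed.errors import DegenerateInputError, InvalidRegionError
from ftirseed.features import (
    FeatureRegion,
    featurize,
    featurize_batch,
    region_energy,
    select_regions,
)
from ftirseed.preprocess import average_replicates, baseline_correct
from ftirseed.synth import BandSpec, GeneratorConfig, generate_spectrum

from conftest import make_flat_spectrum

FIXED_REGIONS = [
    FeatureRegion(3, 40, 60, "d3-r1"),
    FeatureRegion(3, 100, 120, "d3-r2"),
    FeatureRegion(3, 150, 170, "d3-r3"),
    FeatureRegion(4, 20, 40, "d4-r1"),
    FeatureRegion(4, 60, 80, "d4-r2"),
]


class TestRegionEnergy:
    def test_zero_detail_zero_energy(self):
        decomp = dwt_multilevel(np.zeros(512), levels=5)
        assert region_energy(decomp, FeatureRegion(3, 0, 10)) == 0.0

    def test_energy_is_additive_over_split(self):
        decomp = dwt_multilevel(np.random.default_rng(0).normal(size=512), levels=5)
        whole = region_energy(decomp, FeatureRegion(3, 10, 30))
        left = region_energy(decomp, FeatureRegion(3, 10, 20))
        right = region_energy(decomp, FeatureRegion(3, 20, 30))
        assert whole == pytest.approx(left + right)

    def test_tiling_regions_sum_to_detail_energy(self):
        decomp = dwt_multilevel(np.random.default_rng(1).normal(size=512), levels=5)
        n = decomp.details[3].size
        parts = [FeatureRegion(3, i, min(i + 16, n)) for i in range(0, n, 16)]
        total = sum(region_energy(decomp, r) for r in parts)
        assert total == pytest.approx(decomp.detail_energy(3))

    def test_invalid_region_rejected(self):
        decomp = dwt_multilevel(np.zeros(512), levels=5)
        with pytest.raises(InvalidRegionError):
            region_energy(decomp, FeatureRegion(3, 0, 10_000))
        with pytest.raises(InvalidRegionError):
            region_energy(decomp, FeatureRegion(7, 0, 2))


def _single_band_training_set(centers=(3000.0, 2000.0, 1200.0), n_each=6):
    """Three classes, each with its own single disjoint band."""
    bands = [
        BandSpec(centers[0], 30.0, (0.5, 0.0, 0.0)),
        BandSpec(centers[1], 30.0, (0.0, 0.5, 0.0)),
        BandSpec(centers[2], 30.0, (0.0, 0.0, 0.5)),
    ]
    cfg = GeneratorConfig(
        bands=bands, noise_sd=0.001, batch_shift_sd=0.0, batch_gain_sd=0.0,
        baseline_offset_range=(0.0, 0.0), baseline_slope_range=(0.0, 0.0),
    )
    decomps, labels = [], []
    for class_id in (1, 2, 3):
        for i in range(n_each):
            s = generate_spectrum(cfg, class_id, "jinhua", 50 * class_id + i, 1)
            decomps.append(dwt_multilevel(s.absorbance, levels=5, grid=s.grid))
            labels.append(class_id)
    return decomps, labels, centers


class TestSelectRegions:
    def test_counts_and_levels(self, small_dataset):
        from ftirseed.pipeline import _specimen_spectra

        specimens = [s for s in _specimen_spectra(small_dataset) if s.split == "train"]
        decomps = [dwt_multilevel(s.absorbance, levels=5, grid=s.grid) for s in specimens]
        regions = select_regions(decomps, [s.class_id for s in specimens])
        assert sum(r.level == 3 for r in regions) == 3
        assert sum(r.level == 4 for r in regions) == 2

    def test_deterministic(self):
        decomps, labels, _ = _single_band_training_set()
        assert select_regions(decomps, labels) == select_regions(decomps, labels)

    def test_regions_cover_discriminative_bands(self):
        decomps, labels, centers = _single_band_training_set()
        regions = select_regions(decomps, labels)
        d3 = [r for r in regions if r.level == 3]
        intervals = []
        for r in d3:
            hi, _ = coeff_to_wavenumber(decomps[0], 3, r.start)
            _, lo = coeff_to_wavenumber(decomps[0], 3, r.end - 1)
            intervals.append((lo, hi))
        # allow one coefficient (16 cm-1) of slack at the run edges
        for c in centers:
            assert any(lo - 16 <= c <= hi + 16 for lo, hi in intervals), (c, intervals)

    def test_single_class_rejected(self):
        decomps, labels, _ = _single_band_training_set(n_each=3)
        with pytest.raises(DegenerateInputError):
            select_regions(decomps[:3], [1, 1, 1])


class TestFeaturize:
    def test_zero_spectrum_gives_zero_vector(self):
        s = make_flat_spectrum(np.zeros(2048))
        fv = featurize(s, FIXED_REGIONS)
        assert np.array_equal(fv.energies, np.zeros(5))

    def test_scaling_spectrum_scales_energies_quadratically(self, specimen_spectrum):
        from dataclasses import replace

        fv1 = featurize(specimen_spectrum, FIXED_REGIONS)
        fv2 = featurize(
            replace(specimen_spectrum, absorbance=2.0 * specimen_spectrum.absorbance),
            FIXED_REGIONS,
        )
        assert np.allclose(fv2.energies, 4.0 * fv1.energies, rtol=1e-10)

    def test_linear_ramp_barely_changes_energies(self, specimen_spectrum):
        from dataclasses import replace

        base = featurize(specimen_spectrum, FIXED_REGIONS).energies
        ramp = np.linspace(0.0, 0.1, specimen_spectrum.grid.n_points)
        ramped = replace(
            specimen_spectrum, absorbance=specimen_spectrum.absorbance + ramp
        )
        with_ramp = featurize(ramped, FIXED_REGIONS).energies
        assert np.all(np.abs(with_ramp - base) < 0.01 * np.maximum(base, 1e-12))

    def test_wrong_region_count_rejected(self, specimen_spectrum):
        with pytest.raises(ValueError):
            featurize(specimen_spectrum, FIXED_REGIONS[:4])

    def test_overlapping_regions_rejected(self, specimen_spectrum):
        bad = FIXED_REGIONS[:2] + [FeatureRegion(3, 110, 130)] + FIXED_REGIONS[3:]
        with pytest.raises(ValueError):
            featurize(specimen_spectrum, bad)

    def test_same_class_vectors_closer_than_cross_class(self, gen_config):
        def specimen(class_id, sid):
            reps = [
                generate_spectrum(gen_config, class_id, "jinhua", sid, r)
                for r in (1, 2, 3)
            ]
            return baseline_correct(average_replicates(reps))

        a, b = specimen(3, 301), specimen(3, 302)
        c = specimen(1, 303)
        fa = featurize(a, FIXED_REGIONS).energies
        fb = featurize(b, FIXED_REGIONS).energies
        fc = featurize(c, FIXED_REGIONS).energies
        assert np.linalg.norm(fa - fb) < np.linalg.norm(fa - fc)


def test_class3_linearly_separable_on_default_features(small_dataset):
    """Sanity floor: the distinct class separates linearly in feature space."""
    from sklearn.linear_model import LogisticRegression

    from ftirseed.pipeline import _specimen_spectra

    specimens = _specimen_spectra(small_dataset)
    decomps = [
        dwt_multilevel(s.absorbance, levels=5, grid=s.grid)
        for s in specimens
        if s.split == "train"
    ]
    labels = [s.class_id for s in specimens if s.split == "train"]
    regions = select_regions(decomps, labels)
    feats = featurize_batch(specimens, regions)
    X = feats[[f"S{i+1}" for i in range(5)]].to_numpy()
    X = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    y = (feats["class_id"] == 3).astype(int)
    clf = LogisticRegression(max_iter=2000).fit(X, y)
    assert clf.score(X, y) == 1.0
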