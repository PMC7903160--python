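"""Phantom generator: determinism, acquisition-effect semantics and the
statistical structure (scanner signal, age signal, confound correlations)."""

import numpy as np
import pytest

from unlearn.synthetic import (ScannerEffect, StudyDesign, default_effects,
                               describe_dataset, generate_dataset,
                               generate_phantom, three_site_design,
                               two_site_overlap_design)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        eff = default_effects(1)[0]
        a1, t1 = generate_phantom(55.0, 1, eff, 32, seed=9)
        a2, t2 = generate_phantom(55.0, 1, eff, 32, seed=9)
        assert np.array_equal(a1, a2)
        assert np.array_equal(t1, t2)
        a3, _ = generate_phantom(55.0, 1, eff, 32, seed=10)
        assert not np.array_equal(a1, a3)

    def test_doubling_intensity_scale_doubles_prenoise_mean(self):
        eff1 = ScannerEffect(intensity_scale=1.0, contrast_gamma=1.3,
                             bias_amplitude=0.1, bias_coeffs=(0.5, -0.2, 0.1, 0.3))
        eff2 = ScannerEffect(intensity_scale=2.0, contrast_gamma=1.3,
                             bias_amplitude=0.1, bias_coeffs=(0.5, -0.2, 0.1, 0.3))
        i1, _ = generate_phantom(50.0, 0, eff1, 32, seed=0)
        i2, _ = generate_phantom(50.0, 0, eff2, 32, seed=0)
        assert i2.mean() == pytest.approx(2.0 * i1.mean())

    def test_inner_cavity_radius_increases_with_age(self):
        eff = ScannerEffect()
        size = 64
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.sqrt((xx - c) ** 2 + (yy - c) ** 2) / size
        areas = []
        for age in range(40, 91, 10):
            _, tissue = generate_phantom(float(age), 0, eff, size, seed=1)
            areas.append(int(((tissue == 1) & (r < 0.2)).sum()))
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_tissue_map_noise_free_and_categorical(self):
        eff = ScannerEffect(noise_sd=0.5)
        _, t1 = generate_phantom(60.0, 1, eff, 32, seed=1)
        _, t2 = generate_phantom(60.0, 1, eff, 32, seed=2)
        assert np.array_equal(t1, t2)
        assert set(np.unique(t1)) <= {0, 1, 2, 3}

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(50.0, 0, ScannerEffect(), size=8)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            ScannerEffect(intensity_scale=0.0)
        with pytest.raises(ValueError):
            ScannerEffect(noise_sd=-1.0)


class TestGenerateDataset:
    def test_counts_and_domain_labels(self, tiny_dataset):
        assert tiny_dataset.per_domain_counts == {1: 20, 2: 20, 3: 20}

    def test_overlap_design_age_windows(self):
        design = two_site_overlap_design(overlap_years=10.0, n_per_site=200, seed=0)
        (lo1, hi1), (lo2, hi2) = design.age_ranges
        assert hi1 - lo2 == pytest.approx(10.0)
        ds = generate_dataset(design)
        ages = {d: [] for d in (1, 2)}
        for s in ds:
            ages[s.domain_label].append(s.main_label)
        assert min(ages[1]) >= lo1 and max(ages[1]) <= hi1
        assert min(ages[2]) >= lo2 and max(ages[2]) <= hi2

    def test_site_correlated_sex_fraction(self):
        n = 400
        design = StudyDesign(n_sites=2, per_site_n=[n, n], size=16,
                             sex_site_correlation=0.8, seed=5)
        ds = generate_dataset(design)
        sexes = ds.confound("sex")
        didx = ds.domain_index
        frac1 = sexes[didx == 0].mean()
        sd = np.sqrt(0.8 * 0.2 / n)
        assert abs(frac1 - 0.8) < 3 * sd

    def test_age_correlated_sex(self):
        design = StudyDesign(n_sites=2, per_site_n=[300, 300], size=16,
                             sex_age_correlation=0.8, seed=2)
        ds = generate_dataset(design)
        ages = np.array([s.main_label for s in ds])
        sexes = ds.confound("sex")
        median = np.median(ages)
        assert sexes[ages > median].mean() > 0.7
        assert sexes[ages < median].mean() < 0.3

    def test_semi_supervised_label_availability(self):
        design = StudyDesign(n_sites=2, per_site_n=[30, 30], size=16,
                             label_availability=[1.0, 0.0], seed=1)
        ds = generate_dataset(design)
        for s in ds:
            if s.domain_label == 2:
                assert not s.in_p and s.main_label is None
            else:
                assert s.in_p

    def test_images_standardised(self, tiny_dataset):
        for s in list(tiny_dataset)[:5]:
            assert abs(s.image.mean()) < 1e-9
            assert s.image.std() == pytest.approx(1.0)

    def test_correlation_fraction_bounds(self):
        with pytest.raises(ValueError):
            StudyDesign(n_sites=2, per_site_n=[5, 5], sex_site_correlation=0.3)

    def test_both_confound_schemes_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(n_sites=2, per_site_n=[5, 5],
                        sex_site_correlation=0.8, sex_age_correlation=0.8)


class TestDescribeDataset:
    def test_summary_matches_design(self, tiny_dataset):
        df = describe_dataset(tiny_dataset)
        assert list(df["n"]) == [20, 20, 20]
        assert (df["label_fraction"] == 1.0).all()

    def test_balanced_sex_fractions(self):
        ds = generate_dataset(StudyDesign(n_sites=2, per_site_n=[400, 400],
                                          size=16, seed=8))
        df = describe_dataset(ds)
        sd = np.sqrt(0.25 / 400)
        assert np.all(np.abs(df["male_fraction"] - 0.5) < 4 * sd)

    def test_zero_label_site_reported(self):
        ds = generate_dataset(StudyDesign(n_sites=2, per_site_n=[10, 10], size=16,
                                          label_availability=[1.0, 0.0], seed=0))
        df = describe_dataset(ds)
        assert df.loc[df.site == 2, "label_fraction"].item() == 0.0


class TestGeneratorStatisticalStructure:
    """Validates that the generator produces (only) the intended signals,
    using an independent classifier (sklearn logistic regression) on raw
    pixels rather than the package's own probe."""

    def _site_accuracy(self, design):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        ds = generate_dataset(design)
        X = ds.images.reshape(len(ds), -1)
        y = ds.domain_index
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.3, random_state=0,
                                              stratify=y)
        clf = LogisticRegression(max_iter=500).fit(Xtr, ytr)
        return clf.score(Xte, yte)

    def test_distinct_effects_are_detectable(self):
        design = StudyDesign(n_sites=2, per_site_n=[80, 80], size=16, seed=4)
        assert self._site_accuracy(design) > 0.9

    def test_identical_effects_leave_no_site_signal(self):
        eff = default_effects(1)[0]
        design = StudyDesign(n_sites=2, per_site_n=[80, 80], size=16, seed=4,
                             effects=[eff, eff])
        acc = self._site_accuracy(design)
        # 99% binomial interval around chance at n_eval = 48
        assert abs(acc - 0.5) < 2.58 * np.sqrt(0.25 / 48)

    def test_age_signal_recoverable_within_one_site(self):
        from sklearn.linear_model import Ridge
        from sklearn.model_selection import train_test_split

        design = StudyDesign(n_sites=2, per_site_n=[150, 2], size=16, seed=6)
        ds = generate_dataset(design)
        keep = ds.domain_index == 0
        X = ds.images.reshape(len(ds), -1)[keep]
        y = np.array([s.main_label for s in ds])[keep]
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.3, random_state=0)
        pred = Ridge(alpha=10.0).fit(Xtr, ytr).predict(Xte)
        mae = np.abs(pred - yte).mean()
        assert mae < np.std(y) / 2
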