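"""Rat isoeffect analysis: normalization, Fe-plot and direct fits."""

import numpy as np
import pytest

from cordtol.datasets import D50Point, RatDataset
from cordtol.lq import LQParameters, dose_for_bed_at_n
from cordtol.ratfit import (
    EstimationError,
    bootstrap_linear_ci,
    linear_fit,
    nonlinear_fit,
    normalize,
    published_reference,
    single_fraction_grand_mean,
    subgroup_summary,
)


def lq_exact_points(alpha_beta, bed50, fractions):
    params = LQParameters(alpha_beta)
    return [D50Point(dose_for_bed_at_n(bed50, n, params), n) for n in fractions]


class TestNormalization:
    def test_grand_mean_matches_reported_value(self, rat_datasets):
        # mean of (24.5, 22.4, 19, 24, 25.5, 19.5)
        assert single_fraction_grand_mean(rat_datasets) == pytest.approx(22.4833, abs=1e-3)

    def test_single_fraction_points_equal_reference_after_normalization(self, rat_datasets):
        norm = normalize(rat_datasets)
        mean = single_fraction_grand_mean(rat_datasets)
        for ds in norm:
            assert ds.single_fraction_d50() == pytest.approx(mean, rel=1e-12)

    def test_van_der_kogel_cervical_factor(self, rat_datasets):
        norm = normalize(rat_datasets)
        vdk = next(ds for ds in norm if ds.study_label == "Van der Kogel (C)")
        assert vdk.normalization_factor == pytest.approx(22.4833 / 19.0, abs=1e-3)

    def test_dataset_already_at_reference_is_unchanged(self, rat_datasets):
        norm = normalize(rat_datasets, reference=24.5)  # Karger's own value
        karger = next(ds for ds in norm if ds.study_label == "Karger")
        assert karger.normalization_factor == pytest.approx(1.0)

    def test_idempotence(self, rat_datasets):
        once = normalize(rat_datasets, reference=20.0)
        twice = normalize(once, reference=20.0)
        for a, b in zip(once, twice):
            for p, q in zip(a.points, b.points):
                assert p.d50 == pytest.approx(q.d50, rel=1e-12)

    def test_scale_equivariance_per_dataset(self, rat_datasets):
        # multiplying one dataset's doses by c>0 leaves its normalized values unchanged
        norm_ref = normalize(rat_datasets, reference=20.0)
        rescaled = [
            ds.scaled(1.7) if ds.study_label == "White" else ds for ds in rat_datasets
        ]
        norm_re = normalize(rescaled, reference=20.0)
        white_a = next(ds for ds in norm_ref if ds.study_label == "White")
        white_b = next(ds for ds in norm_re if ds.study_label == "White")
        for p, q in zip(white_a.points, white_b.points):
            assert p.d50 == pytest.approx(q.d50, rel=1e-12)

    def test_published_reference_is_quality_corrected_mean(self, rat_datasets):
        assert published_reference(rat_datasets) == pytest.approx(22.4833 / 1.12, abs=1e-3)

    def test_missing_single_fraction_point_is_an_error(self):
        ds = RatDataset("X", "lumbar", 365, (D50Point(30, 2), D50Point(40, 4), D50Point(50, 8)))
        with pytest.raises(ValueError, match="single-fraction"):
            normalize([ds])


class TestFitsOnExactData:
    FRACTIONS = [1, 2, 4, 8, 16, 30]

    def test_linear_fit_recovers_truth(self):
        fit = linear_fit(lq_exact_points(3.0, 120.0, self.FRACTIONS))
        assert fit.alpha_beta == pytest.approx(3.0, rel=1e-6)
        assert fit.bed50 == pytest.approx(120.0, rel=1e-6)

    def test_nonlinear_fit_recovers_truth(self):
        fit = nonlinear_fit(lq_exact_points(3.0, 120.0, self.FRACTIONS))
        assert fit.alpha_beta == pytest.approx(3.0, rel=1e-6)
        assert fit.bed50 == pytest.approx(120.0, rel=1e-6)

    def test_linear_and_nonlinear_agree_on_noiseless_data(self):
        pts = lq_exact_points(4.5, 90.0, self.FRACTIONS)
        lin, non = linear_fit(pts), nonlinear_fit(pts)
        assert lin.alpha_beta == pytest.approx(non.alpha_beta, rel=1e-6)
        assert lin.bed50 == pytest.approx(non.bed50, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(EstimationError, match="3 points"):
            linear_fit(lq_exact_points(3.0, 120.0, [1, 2]))

    def test_unextractable_parameters_rejected(self):
        # D50 increasing with dose per fraction → negative slope in the Fe plot
        pts = [D50Point(20, 1), D50Point(18, 2), D50Point(15, 4)]
        with pytest.raises(EstimationError, match="undefined"):
            linear_fit(pts)


class TestAgainstPublishedPerStudy:
    # per-study linear fits of the original data, as published
    EXPECTED = {
        "Karger": (2.3, 286.0),
        "Ang": (2.3, 238.0),
        "Van der Kogel (C)": (2.5, 167.0),
        "White": (4.8, 149.0),
        "Masuda": (5.2, 149.0),
        "Van der Kogel (L)": (4.3, 111.0),
    }

    @pytest.mark.parametrize("label", sorted(EXPECTED))
    def test_per_study_original_linear_fit(self, rat_datasets, label):
        ds = next(d for d in rat_datasets if d.study_label == label)
        fit = linear_fit(ds.points, scope="per_dataset")
        ab, bed = self.EXPECTED[label]
        assert fit.alpha_beta == pytest.approx(ab, abs=0.15)
        assert fit.bed50 == pytest.approx(bed, abs=10.0)

    def test_subgroup_average_alpha_beta(self, rat_datasets):
        original = subgroup_summary(rat_datasets, normalized=False)
        avg = original[original.scope == "average"].set_index("subgroup")["alpha_beta"]
        assert avg["cervical"] == pytest.approx(2.4, abs=0.1)
        assert avg["thoracolumbar"] == pytest.approx(4.8, abs=0.15)

    def test_subgroup_average_after_normalization(self, rat_datasets):
        ref = published_reference(rat_datasets)
        table = subgroup_summary(rat_datasets, normalized=True, reference=ref)
        avg = table[table.scope == "average"].set_index("subgroup")["alpha_beta"]
        assert avg["cervical"] == pytest.approx(2.2, abs=0.15)
        assert avg["thoracolumbar"] == pytest.approx(4.1, abs=0.15)

    def test_summary_contains_pooled_fits_when_normalized(self, rat_datasets):
        table = subgroup_summary(rat_datasets, normalized=True)
        pooled = table[table.scope == "pooled"]
        assert set(pooled.method) == {"linear", "nonlinear"}
        assert len(pooled) == 4  # two subgroups × two methods


class TestConfidenceIntervals:
    def test_delta_and_bootstrap_agree_roughly(self, normalized_published):
        points = [
            p for ds in normalized_published if ds.subgroup == "thoracolumbar" for p in ds.points
        ]
        fit = linear_fit(points)
        ab_ci, bed_ci = bootstrap_linear_ci(points, n_boot=500, seed=7)
        # same order of magnitude and overlapping intervals
        assert ab_ci[0] < fit.alpha_beta < ab_ci[1]
        assert bed_ci[0] < fit.bed50 < bed_ci[1]
        delta_width = fit.alpha_beta_ci[1] - fit.alpha_beta_ci[0]
        boot_width = ab_ci[1] - ab_ci[0]
        assert 0.4 < boot_width / delta_width < 2.5

    def test_ci_brackets_estimate(self, normalized_published):
        points = [p for ds in normalized_published for p in ds.points]
        fit = nonlinear_fit(points)
        assert fit.alpha_beta_ci[0] <= fit.alpha_beta <= fit.alpha_beta_ci[1]
        assert fit.bed50_ci[0] <= fit.bed50 <= fit.bed50_ci[1]
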