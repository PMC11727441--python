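"""Synthetic cohort generation: covariance structure and planted effects."""

import numpy as np
import pytest

from braingraph import CohortSpec, build_block_covariance, sample_cohort
from braingraph.synthetic_cohort import GROUPS, with_effect


def within_between_means(corr, labels):
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(lab), k=1)
    mask = same[iu]
    return corr[iu][mask].mean(), corr[iu][~mask].mean()


class TestBlockCovariance:
    def test_independence_gives_identity(self):
        spec = CohortSpec(n_rois=8, module_sizes=(4, 4), r_within=0.0, r_between=0.0,
                          t_len=20)
        np.testing.assert_array_equal(build_block_covariance(spec, "HC"), np.eye(8))

    def test_two_block_eigenstructure(self):
        """2 modules of 2, r_within=0.6, r_between=0.1: entries as specified
        and smallest eigenvalue 0.4 (eigendecomposition done by hand)."""
        spec = CohortSpec(n_rois=4, module_sizes=(2, 2), r_within=0.6, r_between=0.1,
                          t_len=10)
        cov = build_block_covariance(spec, "HC")
        assert cov[0, 1] == 0.6 and cov[2, 3] == 0.6
        assert cov[0, 2] == cov[0, 3] == cov[1, 2] == 0.1
        assert np.all(np.diag(cov) == 1.0)
        assert np.linalg.eigvalsh(cov)[0] == pytest.approx(0.4, abs=1e-12)

    def test_effect_factor_scales_within_block_entries(self):
        spec = CohortSpec(n_rois=6, module_sizes=(3, 3), r_within=0.6, r_between=0.0,
                          effect_map={"ROT": 0.5, "PT": 1.0, "HC": 1.0}, t_len=20)
        assert build_block_covariance(spec, "ROT")[0, 1] == pytest.approx(0.30)
        assert build_block_covariance(spec, "HC")[0, 1] == pytest.approx(0.60)

    def test_every_generated_covariance_is_psd_or_cleanly_rejected(self):
        """Positive semidefiniteness is asserted on construction; configs it
        cannot hold for (effect pushing within-block below between-block) are
        rejected with the smallest eigenvalue in the diagnostic."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            rw = rng.uniform(0, 0.9)
            spec = CohortSpec(n_rois=12, module_sizes=(4, 4, 4), r_within=rw,
                              r_between=rng.uniform(0, rw), t_len=30,
                              effect_map={"ROT": rng.uniform(0.1, 1.0)})
            for g in GROUPS:
                try:
                    cov = build_block_covariance(spec, g)
                except ValueError as exc:
                    assert "eigenvalue" in str(exc)
                    continue
                assert np.linalg.eigvalsh(cov)[0] >= -1e-10

    def test_invalid_correlations_rejected(self):
        with pytest.raises(ValueError, match="r_between"):
            CohortSpec(n_rois=4, module_sizes=(2, 2), r_within=0.2, r_between=0.5)
        with pytest.raises(ValueError, match="module_sizes"):
            CohortSpec(n_rois=5, module_sizes=(2, 2))


class TestSampling:
    def test_seeded_reproducibility_bit_identical(self, tiny_spec):
        a = sample_cohort(tiny_spec)
        b = sample_cohort(tiny_spec)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            np.testing.assert_array_equal(ra.timeseries, rb.timeseries)
            assert ra.age == rb.age and ra.sex == rb.sex

    def test_enlarging_group_preserves_existing_subjects(self):
        small = CohortSpec(n_per_group=2, n_rois=10, module_sizes=(5, 5), t_len=40, seed=5)
        big = CohortSpec(n_per_group=3, n_rois=10, module_sizes=(5, 5), t_len=40, seed=5)
        a, b = sample_cohort(small), sample_cohort(big)
        np.testing.assert_array_equal(a[0].timeseries, b[0].timeseries)
        np.testing.assert_array_equal(a[1].timeseries, b[1].timeseries)

    def test_short_series_warns(self):
        spec = CohortSpec(n_per_group=1, n_rois=30, module_sizes=(15, 15), t_len=40)
        with pytest.warns(UserWarning, match="unstable"):
            sample_cohort(spec)

    def test_sample_correlation_converges_to_target(self):
        """One long series (T=10,000): sample correlation within 0.05 of the
        population matrix everywhere."""
        spec = CohortSpec(n_per_group=1, n_rois=20, module_sizes=(10, 10),
                          r_within=0.5, r_between=0.1, t_len=10_000, seed=42)
        rec = sample_cohort(spec)[0]
        sample_corr = np.corrcoef(rec.timeseries, rowvar=False)
        target = build_block_covariance(spec, rec.group)
        assert np.abs(sample_corr - target).max() < 0.05

    def test_hc_has_no_clinical_fields(self, tiny_spec):
        cohort = sample_cohort(tiny_spec)
        for rec in cohort:
            if rec.group == "HC":
                assert rec.duration is None and rec.tfi_total is None
            else:
                assert rec.duration is not None
                if rec.group == "ROT":
                    assert rec.duration < 6.0
                else:
                    assert rec.duration >= 6.0

    def test_tinnitus_groups_have_higher_hearing_thresholds(self):
        spec = CohortSpec(n_per_group=40, n_rois=10, module_sizes=(5, 5), t_len=30, seed=8)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = sample_cohort(spec)
        by_group = {g: np.mean([r.avg_ht for r in cohort if r.group == g]) for g in GROUPS}
        assert by_group["ROT"] > by_group["HC"]
        assert by_group["PT"] > by_group["HC"]


class TestPlantedEffect:
    def test_no_effect_groups_indistinguishable(self):
        """With all effect factors 1, group mean within-module sample
        correlations agree to within 0.02 (Monte-Carlo over replicates)."""
        deltas = []
        for rep in range(30):
            spec = CohortSpec(n_per_group=5, n_rois=20, module_sizes=(10, 10),
                              r_within=0.3, r_between=0.1, t_len=240,
                              effect_map={}, seed=1000 + rep)
            labels = spec.module_labels()[1]
            cohort = sample_cohort(spec)
            means = {}
            for g in ("ROT", "HC"):
                vals = [within_between_means(np.corrcoef(r.timeseries, rowvar=False),
                                             labels)[0]
                        for r in cohort if r.group == g]
                means[g] = np.mean(vals)
            deltas.append(means["ROT"] - means["HC"])
        assert abs(np.mean(deltas)) < 0.02

    def test_planted_deficit_detected_in_most_replicates(self):
        """ROT effect 0.5 lowers ROT within-module correlation below HC in
        >= 95% of replicates."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = CohortSpec(n_per_group=5, n_rois=20, module_sizes=(10, 10),
                              r_within=0.3, r_between=0.1, t_len=240,
                              effect_map={"ROT": 0.5}, seed=2000 + rep)
            labels = spec.module_labels()[1]
            cohort = sample_cohort(spec)
            means = {}
            for g in ("ROT", "HC"):
                vals = [within_between_means(np.corrcoef(r.timeseries, rowvar=False),
                                             labels)[0]
                        for r in cohort if r.group == g]
                means[g] = np.mean(vals)
            wins += means["ROT"] < means["HC"]
        assert wins >= 0.95 * n_rep

    def test_effect_monotonicity_on_population_covariance(self):
        spec = CohortSpec(n_rois=10, module_sizes=(5, 5), r_within=0.4,
                          r_between=0.1, t_len=30)
        previous = np.inf
        for factor in (1.0, 0.8, 0.5, 0.2):
            cov = build_block_covariance(with_effect(spec, "ROT", factor), "ROT")
            assert cov[0, 1] < previous
            previous = cov[0, 1]
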