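"""Generator tests: planted structure, PSD repair, artifacts, determinism."""

import numpy as np
import pytest
from statsmodels.stats.correlation_tools import corr_nearest

from rsfc.catalog import default_catalog
from rsfc.synthetic import (
    AcquisitionSpec,
    ArtifactSpec,
    CohortConfig,
    CorrelationTemplate,
    GroupSpec,
    make_correlation_template,
    nearest_correlation,
    simulate_cohort,
    simulate_subject,
)

from conftest import random_symmetric


def block_difference(template, catalog, seed_names):
    """Oracle: mean(seed-PFC) - mean(seed-SM) from the raw planted matrix."""
    names = template.roi_names
    m = template.raw_matrix
    si = [names.index(n) for n in seed_names]
    pi = [names.index(n) for n in catalog.pfc()]
    mi = [names.index(n) for n in catalog.sensory_motor()]
    return m[np.ix_(si, pi)].mean() - m[np.ix_(si, mi)].mean()


class TestCorrelationTemplate:
    def test_blind_block_difference_planted(self, catalog):
        t = make_correlation_template("blind_like", catalog, effect_size=0.15)
        assert block_difference(t, catalog, catalog.secondary_visual()) == pytest.approx(0.15)
        assert block_difference(t, catalog, catalog.v1()) == pytest.approx(0.15)

    def test_sighted_block_difference_planted(self, catalog):
        t = make_correlation_template("sighted_like", catalog, effect_size=0.2)
        assert block_difference(t, catalog, catalog.secondary_visual()) == pytest.approx(-0.2)

    def test_infant_v1_balanced(self, catalog):
        t = make_correlation_template("infant_like", catalog, effect_size=0.15)
        assert block_difference(t, catalog, catalog.v1()) == pytest.approx(0.0)
        assert block_difference(t, catalog, catalog.secondary_visual()) == pytest.approx(0.15)

    def test_laterality_increment_planted(self, catalog):
        for profile, expected in (("blind_like", 0.12), ("sighted_like", 0.04),
                                  ("infant_like", 0.04)):
            t = make_correlation_template(profile, catalog, effect_size=0.1)
            names = t.roi_names
            m = t.raw_matrix
            within, between = [], []
            for s in catalog.seeds():
                for p in catalog.pfc():
                    val = m[names.index(s), names.index(p)]
                    if catalog.hemisphere(s) == catalog.hemisphere(p):
                        within.append(val)
                    else:
                        between.append(val)
            assert np.mean(within) - np.mean(between) == pytest.approx(expected)

    def test_infant_laterality_equals_sighted(self, catalog):
        ti = make_correlation_template("infant_like", catalog)
        ts = make_correlation_template("sighted_like", catalog)
        assert ti.laterality_increment == ts.laterality_increment

    def test_out_of_range_effect_rejected(self, catalog):
        with pytest.raises(ValueError, match="reduce effect_size"):
            make_correlation_template("blind_like", catalog, effect_size=2.0)

    def test_template_invariants(self, catalog):
        for profile in ("sighted_like", "blind_like", "infant_like"):
            t = make_correlation_template(profile, catalog, effect_size=0.15)
            assert np.allclose(t.matrix, t.matrix.T)
            assert np.allclose(np.diag(t.matrix), 1.0)
            assert np.linalg.eigvalsh(t.matrix).min() >= -1e-8
            off = t.matrix[~np.eye(len(t.roi_names), dtype=bool)]
            assert np.all(np.abs(off) < 1.0)

    def test_unknown_profile_rejected(self, catalog):
        with pytest.raises(ValueError):
            make_correlation_template("martian_like", catalog)


class TestNearestCorrelation:
    def test_psd_input_is_fixed_point(self, catalog):
        t = make_correlation_template("blind_like", catalog, effect_size=0.1)
        repaired, dist = nearest_correlation(t.matrix)
        assert np.allclose(repaired, t.matrix, atol=1e-9)
        assert dist < 1e-8

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(20):
            a = random_symmetric(rng, 8, scale=0.9)
            mine, _ = nearest_correlation(a, tol=1e-12)
            oracle = corr_nearest(a, threshold=1e-12, n_fact=1000)
            assert np.allclose(mine, oracle, atol=1e-5)

    def test_entry_moves_bounded_by_distance(self, rng):
        for _ in range(50):
            a = random_symmetric(rng, 6, scale=0.95)
            repaired, dist = nearest_correlation(a)
            assert np.max(np.abs(repaired - a)) <= dist + 1e-12
            assert np.allclose(np.diag(repaired), 1.0)
            assert np.linalg.eigvalsh(repaired).min() >= -1e-8

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            nearest_correlation(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestSimulateSubject:
    def test_fc_converges_to_template(self, blind_template):
        # Monte-Carlo convergence: at T=20000 the Fisher-z SE is ~0.007,
        # so a 0.05 max-abs tolerance is ~7 SE even after max over pairs.
        acq = AcquisitionSpec(n_frames=20000, tr_seconds=0.392, cohort="infant")
        rec = simulate_subject(blind_template, acq, ArtifactSpec(seed=11))
        fc = np.corrcoef(rec.roi_series, rowvar=False)
        assert np.max(np.abs(fc - blind_template.matrix)) < 0.05

    def test_spike_count_planted(self, blind_template):
        acq = AcquisitionSpec(n_frames=200, tr_seconds=0.392)
        rec = simulate_subject(
            blind_template, acq, ArtifactSpec(n_motion_spikes=3, seed=5)
        )
        assert len(rec.ground_truth["spike_frames"]) == 3
        assert all(1 <= f < 200 for f in rec.ground_truth["spike_frames"])

    def test_same_seed_bit_identical(self, blind_template):
        acq = AcquisitionSpec(n_frames=150, tr_seconds=2.0, cohort="sighted")
        spec = ArtifactSpec(n_motion_spikes=2, drift_slope=0.01,
                            nuisance_weight=0.3, seed=42)
        a = simulate_subject(blind_template, acq, spec)
        b = simulate_subject(blind_template, acq, spec)
        assert np.array_equal(a.roi_series, b.roi_series)
        assert np.array_equal(a.csf_series, b.csf_series)
        assert np.array_equal(a.parcel_means, b.parcel_means)

    def test_drift_recovered_by_regression(self, blind_template):
        acq = AcquisitionSpec(n_frames=500, tr_seconds=0.392)
        rec = simulate_subject(blind_template, acq, ArtifactSpec(drift_slope=0.05, seed=3))
        t = np.arange(500)
        slope = np.polyfit(t, rec.roi_series[:, 0], 1)[0]
        assert slope == pytest.approx(0.05, abs=0.02)

    def test_nuisance_shared_with_compartments(self, blind_template):
        acq = AcquisitionSpec(n_frames=2000, tr_seconds=0.392)
        rec = simulate_subject(
            blind_template, acq, ArtifactSpec(nuisance_weight=0.5, seed=9)
        )
        sources = rec.ground_truth["nuisance_sources"]
        roi_corr = [abs(np.corrcoef(rec.roi_series[:, 0], sources[:, j])[0, 1])
                    for j in range(sources.shape[1])]
        csf_corr = [abs(np.corrcoef(rec.csf_series[:, 0], sources[:, j])[0, 1])
                    for j in range(sources.shape[1])]
        assert max(roi_corr) > 0.2
        assert max(csf_corr) > 0.5

    def test_dropout_roi_intensity_low(self, blind_template):
        acq = AcquisitionSpec(n_frames=100, tr_seconds=0.392)
        roi = blind_template.roi_names[4]
        rec = simulate_subject(
            blind_template, acq, ArtifactSpec(dropout_rois=(roi,), seed=2)
        )
        mu = rec.parcel_means.mean()
        sd = rec.parcel_means.std(ddof=1)
        assert rec.roi_mean_intensity[roi] < mu - 3 * sd
        others = [v for k, v in rec.roi_mean_intensity.items() if k != roi]
        assert min(others) > mu - 3 * sd

    def test_unknown_dropout_roi_rejected(self, blind_template):
        acq = AcquisitionSpec(n_frames=100, tr_seconds=0.392)
        with pytest.raises(ValueError, match="dropout_rois"):
            simulate_subject(blind_template, acq, ArtifactSpec(dropout_rois=("nope",)))

    def test_ar1_preserves_cross_correlation(self, blind_template):
        acq = AcquisitionSpec(n_frames=20000, tr_seconds=0.392)
        rec = simulate_subject(blind_template, acq, ArtifactSpec(seed=13), ar1=0.4)
        fc = np.corrcoef(rec.roi_series, rowvar=False)
        assert np.max(np.abs(fc - blind_template.matrix)) < 0.08
        col = rec.roi_series[:, 0]
        lag1 = np.corrcoef(col[:-1], col[1:])[0, 1]
        assert lag1 == pytest.approx(0.4, abs=0.05)


class TestArtifactSpecValidation:
    def test_negative_spikes_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(n_motion_spikes=-1)

    def test_nuisance_weight_range(self):
        with pytest.raises(ValueError):
            ArtifactSpec(nuisance_weight=1.0)
        ArtifactSpec(nuisance_weight=0.0)

    def test_acquisition_validation(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(n_frames=3, tr_seconds=1.0)
        with pytest.raises(ValueError):
            AcquisitionSpec(n_frames=100, tr_seconds=0.0)


def small_cohort_config(master_seed=0, **overrides):
    groups = {
        "sighted": GroupSpec(n=4, profile="sighted_like", n_frames=60, tr_seconds=2.0),
        "blind": GroupSpec(n=3, profile="blind_like", n_frames=60, tr_seconds=2.0),
        "infant": GroupSpec(n=5, profile="infant_like", n_frames=80, tr_seconds=0.392),
    }
    groups.update(overrides)
    return CohortConfig(groups=groups, master_seed=master_seed)


class TestSimulateCohort:
    def test_study_cohort_sizes(self):
        # 50 + 30 + 475 = 555 subjects at the study's group sizes.
        cfg = CohortConfig(
            groups={
                "sighted": GroupSpec(n=50, profile="sighted_like", n_frames=20,
                                     tr_seconds=2.0),
                "blind": GroupSpec(n=30, profile="blind_like", n_frames=20,
                                   tr_seconds=2.0),
                "infant": GroupSpec(n=475, profile="infant_like", n_frames=20,
                                    tr_seconds=0.392),
            },
            master_seed=1,
        )
        recordings, ledger = simulate_cohort(cfg)
        assert ledger["n_subjects"] == 555
        assert len(recordings) == 555
        counts = {g: sum(1 for s in ledger["subjects"] if s["group"] == g)
                  for g in ("sighted", "blind", "infant")}
        assert counts == {"sighted": 50, "blind": 30, "infant": 475}

    def test_planted_exclusions_marked(self):
        cfg = small_cohort_config(
            infant=GroupSpec(n=12, profile="infant_like", n_frames=200,
                             tr_seconds=0.392, n_excluded_motion=5)
        )
        _, ledger = simulate_cohort(cfg)
        marked = [s for s in ledger["subjects"] if s["intended_exclusion"]]
        assert len(marked) == 5
        assert all(s["exclusion_reason"] == "motion" for s in marked)
        # >10% of frames spiked for each planted exclusion
        assert all(s["n_spikes"] > 20 for s in marked)

    def test_same_master_seed_identical_ledgers(self):
        _, ledger_a = simulate_cohort(small_cohort_config(master_seed=7))
        _, ledger_b = simulate_cohort(small_cohort_config(master_seed=7))
        assert ledger_a == ledger_b

    def test_different_master_seed_differs(self):
        rec_a, _ = simulate_cohort(small_cohort_config(master_seed=1))
        rec_b, _ = simulate_cohort(small_cohort_config(master_seed=2))
        assert not np.array_equal(rec_a[0].roi_series, rec_b[0].roi_series)

    def test_ledger_block_differences(self, catalog):
        _, ledger = simulate_cohort(small_cohort_config())
        assert ledger["groups"]["blind"]["true_block_difference"]["secondary_visual"] == (
            pytest.approx(0.15)
        )
        assert ledger["groups"]["sighted"]["true_block_difference"]["V1"] == (
            pytest.approx(-0.15)
        )
        assert ledger["groups"]["infant"]["true_block_difference"]["V1"] == pytest.approx(0.0)

    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(n=0, profile="blind_like", n_frames=50, tr_seconds=2.0)


def test_sign_recovery_small_sweep(catalog):
    """Planted block differences recovered in sign (reduced-scale sweep)."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = CohortConfig(
            groups={
                "blind": GroupSpec(n=30, profile="blind_like", n_frames=300,
                                   tr_seconds=0.392, effect_size=0.15),
            },
            master_seed=seed,
        )
        recordings, _ = simulate_cohort(cfg)
        diffs = []
        for rec in recordings:
            fc = np.corrcoef(rec.roi_series, rowvar=False)
            names = rec.roi_names
            si = [names.index(n) for n in catalog.secondary_visual()]
            pi = [names.index(n) for n in catalog.pfc()]
            mi = [names.index(n) for n in catalog.sensory_motor()]
            diffs.append(fc[np.ix_(si, pi)].mean() - fc[np.ix_(si, mi)].mean())
        if np.mean(diffs) > 0:
            hits += 1
    assert hits == n_seeds
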