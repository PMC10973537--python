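"""Synthetic-cohort generator: planted axis, covariance model, determinism."""

import numpy as np
import pandas as pd
import pytest

from gradhier.atlas import ValidationError, default_parcellation
from gradhier.simulate import (
    HierarchySpec,
    SimulationConfig,
    build_covariance,
    build_latent_axis,
    simulate_clinical_scores,
    simulate_cohort,
    simulate_subject_timeseries,
)

from .oracles import brute_force_covariance


class TestLatentAxis:
    def test_default_orientation_sensorimotor_low_default_high(self, atlas20):
        spec = HierarchySpec()
        assert spec.network_centers["Default"] == max(spec.network_centers.values())
        assert spec.network_centers["Somatomotor"] == min(spec.network_centers.values())

    def test_kappa_one_is_identity(self, atlas20, rng):
        spec = HierarchySpec()
        state = rng.bit_generator.state
        g1 = build_latent_axis(atlas20, spec, np.random.default_rng(1), kappa=1.0)
        g2 = build_latent_axis(atlas20, spec, np.random.default_rng(1), kappa=1.0)
        np.testing.assert_array_equal(g1, g2)

    def test_kappa_zero_collapses_to_mean(self, atlas20):
        with pytest.raises(ValidationError):
            SimulationConfig(contraction_kappa=0.0)  # config forbids kappa = 0
        # the affine map itself degenerates cleanly at kappa -> 0
        g = build_latent_axis(atlas20, HierarchySpec(), np.random.default_rng(3), kappa=1e-12)
        assert np.ptp(g) < 1e-9

    def test_contraction_scales_range_by_kappa(self, atlas200):
        spec = HierarchySpec()
        full = build_latent_axis(atlas200, spec, np.random.default_rng(5), kappa=1.0)
        shrunk = build_latent_axis(atlas200, spec, np.random.default_rng(5), kappa=0.6)
        assert np.ptp(shrunk) == pytest.approx(0.6 * np.ptp(full), rel=1e-12)
        np.testing.assert_allclose(shrunk.mean(), full.mean(), atol=1e-12)

    def test_network_kappa_contracts_only_named_network(self, atlas200):
        spec = HierarchySpec()
        full = build_latent_axis(atlas200, spec, np.random.default_rng(5), kappa=1.0)
        dmn_only = build_latent_axis(
            atlas200, spec, np.random.default_rng(5), kappa=1.0,
            network_kappa={"Default": 0.6},
        )
        dmn = atlas200.parcels_in("Default")
        other = np.setdiff1d(np.arange(200), dmn)
        np.testing.assert_array_equal(full[other], dmn_only[other])
        assert (np.abs(dmn_only[dmn] - full.mean()) < np.abs(full[dmn] - full.mean())).all()

    def test_unknown_network_rejected(self, atlas20):
        spec = HierarchySpec(network_centers={"Visual": 0.0, "Default": 1.0})
        with pytest.raises(ValidationError, match="no latent center"):
            build_latent_axis(atlas20, spec, np.random.default_rng(0))


class TestCovariance:
    def test_matches_brute_force_formula(self, rng):
        meta = default_parcellation(20)
        spec = HierarchySpec(length_scale=1.0, within_network_boost=0.2)
        g = build_latent_axis(meta, spec, rng)
        cov = build_covariance(g, meta, spec)
        oracle = brute_force_covariance(g, meta.network_of(), 1.0, 0.2)
        # oracle lacks the PD jitter; any difference must be a diagonal shift
        np.testing.assert_allclose(
            cov - np.diag(np.diag(cov)), oracle - np.diag(np.diag(oracle)), atol=1e-12
        )
        assert (np.diag(cov) >= np.diag(oracle) - 1e-12).all()

    def test_same_latent_same_network_entry(self, atlas20):
        spec = HierarchySpec(within_network_boost=0.2)
        g = np.zeros(20)
        cov = build_covariance(g, atlas20, spec)
        same = atlas20.parcels_in("Default")[:2]
        assert cov[same[0], same[1]] == pytest.approx(1.2)

    def test_distant_different_network_entry_decays(self, atlas20):
        spec = HierarchySpec(within_network_boost=0.0)
        g = np.linspace(0, 50, 20)
        cov = build_covariance(g, atlas20, spec)
        assert cov[0, -1] < 1e-10

    def test_positive_definite_after_jitter(self, atlas200, rng):
        spec = HierarchySpec()
        g = build_latent_axis(atlas200, spec, rng)
        cov = build_covariance(g, atlas200, spec)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_bad_length_scale_rejected(self):
        with pytest.raises(ValidationError):
            HierarchySpec(length_scale=0.0)


class TestTimeSeriesSampling:
    def test_sample_correlation_converges_to_model(self, rng):
        meta = default_parcellation(14)
        spec = HierarchySpec()
        g = build_latent_axis(meta, spec, rng)
        cov = build_covariance(g, meta, spec)
        ts = simulate_subject_timeseries(cov, 20000, np.random.default_rng(11))
        target = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        sample = np.corrcoef(ts.values, rowvar=False)
        assert np.abs(sample - target).max() < 0.03

    def test_identity_covariance_uncorrelated(self):
        ts = simulate_subject_timeseries(np.eye(10), 20000, np.random.default_rng(2))
        r = np.corrcoef(ts.values, rowvar=False)
        off = r[~np.eye(10, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_same_seed_identical(self):
        cov = np.eye(5) + 0.3
        a = simulate_subject_timeseries(cov, 50, np.random.default_rng(9))
        b = simulate_subject_timeseries(cov, 50, np.random.default_rng(9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValidationError, match="jitter"):
            simulate_subject_timeseries(bad, 10, np.random.default_rng(0))


class TestClinicalScores:
    def test_noise_free_scores_decrease_in_dmn(self):
        dmn = np.linspace(0, 1, 30)
        cesd, hamd = simulate_clinical_scores(
            dmn, 38.0, 32.0, 0.0, np.random.default_rng(0)
        )
        assert (np.diff(cesd) <= 0).all() and (np.diff(hamd) <= 0).all()
        assert cesd[0] > cesd[-1]

    def test_zero_slope_decouples(self):
        rng = np.random.default_rng(4)
        dmn = rng.normal(size=4000)
        cesd, _ = simulate_clinical_scores(dmn, 30.0, 0.0, 5.0, rng)
        assert abs(np.corrcoef(dmn, cesd)[0, 1]) < 0.05

    def test_case_group_median_matches_design(self):
        """Default coupling lands case CESD ~ 19 / control ~ 6 (HAMD 9 / 3)."""
        sim = simulate_cohort(
            SimulationConfig(n_parcels=40, n_per_group=200, n_timepoints=4,
                             network_kappa={"Default": 0.6}, seed=123)
        )
        med = sim.cohort.table.groupby("group")[["cesd", "hamd"]].median()
        assert abs(med.loc["case", "cesd"] - 19) <= 2
        assert abs(med.loc["control", "cesd"] - 6) <= 2
        assert abs(med.loc["case", "hamd"] - 9) <= 2
        assert abs(med.loc["control", "hamd"] - 3) <= 2

    def test_cesd_clipped_to_legal_range(self):
        cesd, hamd = simulate_clinical_scores(
            np.array([-10.0, 10.0]), 38.0, 32.0, 0.0, np.random.default_rng(0)
        )
        assert cesd.max() <= 60 and cesd.min() >= 0 and hamd.min() >= 0


class TestCohortAssembly:
    def test_design_counts(self, small_cohort):
        t = small_cohort.cohort.table
        assert len(t) == 10
        assert (t["group"].value_counts() == 5).all()
        assert len(small_cohort.timeseries) == 10

    def test_null_configuration_has_no_planted_effect(self):
        config = SimulationConfig(
            n_parcels=20, n_per_group=4, n_timepoints=8,
            contraction_kappa=1.0, clinical_slope=0.0, seed=5,
        )
        sim = simulate_cohort(config)
        np.testing.assert_array_equal(
            sim.ground_truth.latent_axis["control"],
            sim.ground_truth.latent_axis["case"],
        )
        assert sim.ground_truth.clinical_coupling_sign == 0

    def test_contracted_case_axis_strictly_narrower(self):
        config = SimulationConfig(
            n_parcels=20, n_per_group=4, n_timepoints=8,
            contraction_kappa=0.6, seed=5,
        )
        sim = simulate_cohort(config)
        truth = sim.ground_truth
        assert np.ptp(truth.latent_axis["case"]) < np.ptp(truth.latent_axis["control"])

    def test_fixed_seed_reproduces_exactly(self):
        config = SimulationConfig(n_parcels=20, n_per_group=3, n_timepoints=10, seed=77)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        for ta, tb in zip(a.timeseries, b.timeseries, strict=True):
            np.testing.assert_array_equal(ta.values, tb.values)
        pd.testing.assert_frame_equal(a.cohort.table, b.cohort.table)

    def test_connectivity_output_mode(self):
        config = SimulationConfig(n_parcels=20, n_per_group=3, n_timepoints=30, seed=7)
        sim = simulate_cohort(config, output="connectivity")
        assert sim.timeseries is None
        assert len(sim.connectivity) == 6
        assert sim.connectivity[0].value_kind == "pearson_r"
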