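"""Generator contracts: determinism, calibration, ground-truth totality."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

import fibroscreen as fs
from fibroscreen.synthgen import ConfigurationError, PlacementError


class TestScreenSimulation:
    def test_identical_seed_identical_tables(self):
        cfg = fs.ScreenConfig(n_donors=2, wells_per_condition=10, seed=1,
                              shrna_panel=fs.uniform_panel(3, 2))
        pm1, wt1, _ = fs.simulate_screen(cfg)
        pm2, wt2, _ = fs.simulate_screen(cfg)
        pdt.assert_frame_equal(pm1, pm2)
        pdt.assert_frame_equal(wt1, wt2)

    def test_zero_noise_negative_controls_exactly_one(self):
        cfg = fs.ScreenConfig(n_donors=1, wells_per_condition=5, cv_noise=0.0, seed=2)
        pm, wt, _ = fs.simulate_screen(cfg)
        neg = wt.merge(pm)[lambda d: d.role == "negative_control"]["score"]
        assert (neg == 1.0).all()

    def test_sample_window_near_fold_separation(self):
        cfg = fs.ScreenConfig(n_donors=1, wells_per_condition=120,
                              fold_separation=3.0, cv_noise=0.10, seed=3)
        pm, wt, _ = fs.simulate_screen(cfg)
        m = wt.merge(pm)
        win = fs.assay_window(
            m.loc[m.role == "negative_control", "score"],
            m.loc[m.role == "positive_control", "score"],
        )
        assert win == pytest.approx(3.0, rel=0.10)

    def test_window_monotone_in_fold_separation(self):
        wins = []
        for fold in (2.0, 3.0, 5.0):
            cfg = fs.ScreenConfig(n_donors=1, wells_per_condition=60,
                                  fold_separation=fold, cv_noise=0.10, seed=4)
            pm, wt, _ = fs.simulate_screen(cfg)
            m = wt.merge(pm)
            wins.append(fs.assay_window(
                m.loc[m.role == "negative_control", "score"],
                m.loc[m.role == "positive_control", "score"],
            ))
        assert wins[0] < wins[1] < wins[2]

    def test_truth_join_is_total(self, small_screen):
        _, pm, wt, truth = small_screen
        joined = wt.merge(truth.well_truth, on=["plate", "well", "donor"])
        assert len(joined) == len(wt)
        assert joined["true_mean_score"].notna().all()

    @pytest.mark.parametrize("bad", [
        dict(fold_separation=1.0), dict(fold_separation=0.5),
        dict(cv_noise=-0.1), dict(wells_per_condition=1),
        dict(shrna_panel=(("G", 1),)), dict(shrna_panel=(("G", 9),)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            fs.simulate_screen(fs.ScreenConfig(**bad))


class TestEfficacyMixture:
    def test_samples_in_unit_interval(self):
        rng = np.random.default_rng(0)
        eff = fs.EfficacyMixture().sample(5000, rng)
        assert eff.min() >= 0.0 and eff.max() <= 1.0

    def test_tail_probability_matches_monte_carlo(self):
        mix = fs.EfficacyMixture()
        rng = np.random.default_rng(1)
        eff = mix.sample(200_000, rng)
        for thr in (0.60, 0.75):
            assert (eff > thr).mean() == pytest.approx(
                mix.tail_probability(thr), abs=0.005
            )

    def test_default_mixture_tail_above_60pct(self):
        # closed-form: 0.8 * truncated-normal tail beyond 0.60
        assert fs.EfficacyMixture().tail_probability(0.60) == pytest.approx(
            0.79, abs=0.01
        )

    def test_point_mass_limit(self):
        mix = fs.EfficacyMixture(w_eff=1.0, eff_mean=0.9, eff_sd=0.0)
        eff = mix.sample(50, np.random.default_rng(2))
        assert eff == pytest.approx(np.full(50, 0.9))


class TestKnockdownPanel:
    def test_no_noise_recovers_definition(self):
        cfg = fs.ScreenConfig(
            n_donors=2, shrna_panel=fs.uniform_panel(10, 3),
            measurement_cv=0.0, seed=5,
        )
        panel, truth = fs.simulate_knockdown_panel(cfg)
        merged = panel.merge(truth.shrna_efficacy, on=["shrna_id", "gene"])
        assert merged["relative_expression"].to_numpy() == pytest.approx(
            1.0 - merged["efficacy"].to_numpy()
        )

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.simulate_knockdown_panel(fs.ScreenConfig(shrna_panel=()))

    def test_deterministic(self):
        cfg = fs.ScreenConfig(shrna_panel=fs.uniform_panel(4, 2), seed=6)
        p1, _ = fs.simulate_knockdown_panel(cfg)
        p2, _ = fs.simulate_knockdown_panel(cfg)
        pdt.assert_frame_equal(p1, p2)


class TestImageRendering:
    def test_empty_scene_is_background(self, noise_free_spec):
        stack, _ = fs.render_well_image(0, 0.0, noise_free_spec, seed=0)
        assert (stack == noise_free_spec.background).all()

    def test_disjoint_nuclei_yield_separate_components(self, noise_free_spec):
        from skimage import measure
        stack, truth = fs.render_well_image(12, 0.0, noise_free_spec, seed=1)
        _, n = measure.label(
            stack[0] > noise_free_spec.background, connectivity=2, return_num=True
        )
        assert n == 12 == len(truth.nuclei_centers)

    def test_asma_signal_linear_in_level(self, noise_free_spec):
        rng_args = dict(spec=noise_free_spec, seed=7)
        s1, _ = fs.render_well_image(8, 1.0, **rng_args)
        s2, _ = fs.render_well_image(8, 2.0, **rng_args)
        bg = noise_free_spec.background
        i1 = (s1[1].astype(float) - bg).sum()
        i2 = (s2[1].astype(float) - bg).sum()
        assert i2 / i1 == pytest.approx(2.0, rel=0.01)

    def test_identical_seed_identical_image(self):
        s1, _ = fs.render_well_image(10, 1.5, fs.ImageSpec(), seed=42)
        s2, _ = fs.render_well_image(10, 1.5, fs.ImageSpec(), seed=42)
        assert np.array_equal(s1, s2)

    def test_impossible_placement_raises(self):
        spec = fs.ImageSpec(shape=(64, 64), min_separation=40)
        with pytest.raises(PlacementError):
            fs.render_well_image(30, 1.0, spec, seed=0)


class TestExpressionStudy:
    def test_full_retention_means_identical_truth(self):
        cfg = fs.StudyConfig(n_probes=200, n_signature=20, retention_fraction=1.0,
                             n_ssc=3, n_healthy=3, seed=8)
        _, _, truth = fs.simulate_expression_study(cfg)
        pt = truth.probe_truth
        assert pt["lfc_p4"].to_numpy() == pytest.approx(pt["lfc_baseline"].to_numpy())

    def test_no_batch_effect_replicates_differ_only_by_noise(self):
        cfg = fs.StudyConfig(
            n_probes=400, n_signature=0, batch_shift_sd=0.0,
            batch_scale_range=(1.0, 1.0), noise_sd=0.25,
            n_ssc=4, n_healthy=4, n_replicates=4, seed=9,
        )
        matrix, meta, _ = fs.simulate_expression_study(cfg)
        reps = meta[meta["replicate_of"] != ""]
        diffs = []
        for _, row in reps.iterrows():
            d = matrix[row["sample_id"]] - matrix[row["replicate_of"]]
            diffs.append(d.to_numpy())
        d = np.concatenate(diffs)
        # difference of two independent residuals: sd = noise_sd * sqrt(2)
        assert abs(d.mean()) < 0.05
        assert d.std() == pytest.approx(cfg.noise_sd * np.sqrt(2), rel=0.10)

    def test_matrix_finite_and_truth_total(self, oracle_study):
        _, matrix, meta, truth = oracle_study
        assert np.isfinite(matrix.to_numpy()).all()
        assert len(truth.probe_truth) == len(matrix)
        assert set(meta["sample_id"]) == set(matrix.columns)
        # replicate samples appear in the opposite batch from their source
        reps = meta[meta["replicate_of"] != ""]
        assert len(reps) == 3
        src_batch = meta.set_index("sample_id")["batch"]
        for _, r in reps.iterrows():
            assert r["batch"] != src_batch[r["replicate_of"]]

    @pytest.mark.parametrize("bad", [
        dict(n_signature=300, n_probes=200), dict(retention_fraction=1.5),
        dict(n_ssc=2), dict(noise_sd=0.0), dict(n_replicates=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            fs.simulate_expression_study(fs.StudyConfig(**bad))
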