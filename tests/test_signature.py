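"""Batch correction, moderated DE and retention metrics.

The numerical reference values in this file were computed with the
Bioconductor reference implementations (limma::eBayes and sva::ComBat,
R 4.3) on the exact matrices the seeded fixture regenerates, and frozen
here; they check the in-package implementations against an independent
code path.
"""

import numpy as np
import pandas as pd
import pytest

import fibroscreen as fs
from fibroscreen.signature import (
    DesignError,
    DEThresholds,
    batch_correct,
    compare_signatures,
    fit_variance_prior,
    moderated_de,
    retention_from_counts,
    select_degs,
)
from fibroscreen.workbench import signature_stage


def _baseline_slice(matrix, meta):
    sel = (meta["passage"] == "P0P1") & (meta["replicate_of"] == "")
    meta_b = meta[sel].reset_index(drop=True)
    return matrix[meta_b["sample_id"].to_numpy()], meta_b


# limma::eBayes on the seed-123 fixture (baseline passage, 5 vs 5)
LIMMA_HYPER = dict(d0=11.2938555315, s0_sq=0.0912625915, v0=55.6451779946)
LIMMA_PROBES = {
    # probe: (log2fc, t, p, lods)
    "probe_00000": (-0.0624441655, -0.2875093012, 7.7678773000e-01, -7.0232744282),
    "probe_00003": (-0.1038705256, -0.6846334858, 5.0171747221e-01, -6.8245417181),
    "probe_00004": (-0.1697883783, -0.8789164863, 3.9026175478e-01, -6.6708994931),
    "probe_00082": (-1.8179783393, -10.7238145183, 1.4290782735e-09, 12.1984579682),
}
LIMMA_N_SIGNIFICANT = 26

# sva::ComBat on the full 300 x 23 two-batch fixture; (row, col) 1-based
COMBAT_CELLS = {
    (1, 1): 6.0869681270, (1, 2): 6.0689076742, (10, 5): 9.6305154045,
    (100, 20): 6.2176580505, (250, 15): 9.6753413308, (300, 23): 4.3464037468,
}
COMBAT_MEAN, COMBAT_SD = 8.5288439506, 2.0527099094


class TestModeratedDEAgainstReference:
    def test_variance_prior_matches_reference(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        mat_b, meta_b = _baseline_slice(matrix, meta)
        res = moderated_de(mat_b, meta_b)
        hyper = res.attrs["eb_hyper"]
        assert hyper.d0 == pytest.approx(LIMMA_HYPER["d0"], rel=1e-6)
        assert hyper.s0_sq == pytest.approx(LIMMA_HYPER["s0_sq"], rel=1e-6)
        assert res.attrs["v0"] == pytest.approx(LIMMA_HYPER["v0"], rel=1e-6)

    def test_per_probe_statistics_match_reference(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        mat_b, meta_b = _baseline_slice(matrix, meta)
        res = moderated_de(mat_b, meta_b)
        for probe, (lfc, t, p, lods) in LIMMA_PROBES.items():
            row = res.loc[probe]
            assert row["log2fc"] == pytest.approx(lfc, abs=1e-8)
            assert row["t"] == pytest.approx(t, rel=1e-6)
            assert row["p"] == pytest.approx(p, rel=1e-6)
            assert row["lods"] == pytest.approx(lods, rel=1e-5)
        assert int(res["significant"].sum()) == LIMMA_N_SIGNIFICANT


class TestBatchCorrectAgainstReference:
    def test_adjusted_cells_match_reference(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        corrected, params = batch_correct(matrix, meta)
        arr = corrected.to_numpy()
        for (i, j), val in COMBAT_CELLS.items():
            assert arr[i - 1, j - 1] == pytest.approx(val, abs=1e-7)
        assert arr.mean() == pytest.approx(COMBAT_MEAN, abs=1e-7)
        assert arr.std(ddof=1) == pytest.approx(COMBAT_SD, abs=1e-7)
        assert params is not None and len(params.batches) == 2


class TestBatchCorrectBehaviour:
    def test_single_batch_is_noop(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        one = meta.assign(batch=1)
        corrected, params = batch_correct(matrix, one)
        pd.testing.assert_frame_equal(corrected, matrix)
        assert params is None

    def test_additive_shift_removed(self):
        cfg = fs.StudyConfig(
            n_probes=400, n_signature=0, batch_shift_sd=0.6,
            batch_scale_range=(1.0, 1.0), noise_sd=0.2,
            n_ssc=6, n_healthy=6, n_replicates=2, seed=17,
        )
        matrix, meta, _ = fs.simulate_expression_study(cfg)
        corrected, _ = batch_correct(matrix, meta)
        b1 = corrected.loc[:, (meta["batch"] == 1).to_numpy()].mean(axis=1)
        b2 = corrected.loc[:, (meta["batch"] == 2).to_numpy()].mean(axis=1)
        gap_before = (
            matrix.loc[:, (meta["batch"] == 1).to_numpy()].mean(axis=1)
            - matrix.loc[:, (meta["batch"] == 2).to_numpy()].mean(axis=1)
        )
        assert np.abs(b1 - b2).mean() < 0.12
        assert np.abs(b1 - b2).mean() < np.abs(gap_before).mean() / 3

    def test_replicate_cross_batch_distance_shrinks(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        corrected, _ = batch_correct(matrix, meta)
        reps = meta[meta["replicate_of"] != ""]

        def mean_dist(m):
            return np.mean([
                np.linalg.norm(m[r["sample_id"]] - m[r["replicate_of"]])
                for _, r in reps.iterrows()
            ])

        assert mean_dist(corrected) < mean_dist(matrix)

    def test_contrast_estimate_unbiased(self):
        """Correction must not distort the disease effect (mean |shift| < 0.05)."""
        cfg = fs.StudyConfig(n_probes=500, n_signature=50, seed=23)
        matrix, meta, truth = fs.simulate_expression_study(cfg)
        corrected, _ = batch_correct(matrix, meta)
        sel = (meta["passage"] == "P0P1") & (meta["replicate_of"] == "")
        meta_b = meta[sel].reset_index(drop=True)
        lfc_raw = moderated_de(matrix[meta_b["sample_id"]], meta_b)["log2fc"]
        lfc_cor = moderated_de(corrected[meta_b["sample_id"]], meta_b)["log2fc"]
        sig = truth.probe_truth.set_index("probe")["is_signature"]
        shift = (lfc_cor - lfc_raw)[sig.to_numpy()]
        assert np.abs(shift.mean()) < 0.05

    def test_confounded_design_rejected(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        confounded = meta.copy()
        confounded["batch"] = np.where(confounded["disease"] == "SSc", 1, 2)
        with pytest.raises(DesignError):
            batch_correct(matrix, confounded)


class TestModeratedDEBehaviour:
    def test_planted_large_effect_is_significant(self):
        rng = np.random.default_rng(3)
        n = 8
        y = rng.normal(8.0, 0.25, size=(500, 2 * n))
        y[0, :n] += 2.0  # planted log2FC = 2
        mat = pd.DataFrame(
            y, index=[f"p{i}" for i in range(500)],
            columns=[f"s{i}" for i in range(2 * n)],
        )
        meta = pd.DataFrame(dict(
            sample_id=mat.columns,
            disease=["SSc"] * n + ["healthy"] * n,
        ))
        res = moderated_de(mat, meta)
        assert bool(res.loc["p0", "significant"])
        assert res.loc["p0", "log2fc"] == pytest.approx(2.0, abs=0.3)

    def test_paired_identical_members_zero_fc(self):
        rng = np.random.default_rng(4)
        base = rng.normal(7, 1, size=(100, 5))
        mat = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"p{i}" for i in range(100)],
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        )
        meta = pd.DataFrame(dict(
            sample_id=mat.columns,
            disease=["SSc"] * 5 + ["healthy"] * 5,
            donor=[f"d{i}" for i in range(5)] * 2,
        ))
        res = moderated_de(mat, meta, paired=True)
        assert res["log2fc"].to_numpy() == pytest.approx(np.zeros(100))

    def test_null_data_false_call_rate(self):
        cfg = fs.StudyConfig(n_probes=2000, n_signature=0, n_ssc=6, n_healthy=6,
                             seed=31)
        matrix, meta, _ = fs.simulate_expression_study(cfg)
        mat_b, meta_b = _baseline_slice(matrix, meta)
        res = moderated_de(mat_b, meta_b)
        assert res["significant"].mean() <= 0.002

    def test_vanishing_noise_recovers_exact_signature(self):
        cfg = fs.StudyConfig(
            n_probes=500, n_signature=40, noise_sd=0.01,
            batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
            baseline_mean_range=(6.0, 12.0), n_ssc=5, n_healthy=5, seed=37,
        )
        matrix, meta, truth = fs.simulate_expression_study(cfg)
        mat_b, meta_b = _baseline_slice(matrix, meta)
        res = moderated_de(mat_b, meta_b)
        selected = set(select_degs(res).index)
        true_set = set(
            truth.probe_truth.loc[truth.probe_truth["is_signature"], "probe"]
        )
        assert selected == true_set

    def test_bh_q_monotone_in_p(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        mat_b, meta_b = _baseline_slice(matrix, meta)
        res = moderated_de(mat_b, meta_b).sort_values("p")
        assert (np.diff(res["q"].to_numpy()) >= -1e-12).all()
        # selection count non-decreasing in alpha
        counts = [(res["q"] < a).sum() for a in (0.001, 0.01, 0.05, 0.25)]
        assert counts == sorted(counts)

    def test_too_few_samples_rejected(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        mat_b, meta_b = _baseline_slice(matrix, meta)
        tiny = meta_b.iloc[[0, 5]]
        with pytest.raises(DesignError):
            moderated_de(mat_b[tiny["sample_id"].to_numpy()], tiny)


class TestSelectionAndComparison:
    def test_composite_rule_gates(self):
        res = pd.DataFrame(
            dict(
                log2fc=[1.0, 1.0, 0.3, 1.0, 1.0],
                q=[0.005, 0.02, 0.005, 0.005, 0.005],
                lods=[2.0, 2.0, 2.0, -1.0, 2.0],
                avg_expr=[6.0, 6.0, 6.0, 6.0, 3.5],
                t=[5.0] * 5, p=[1e-4] * 5,
            ),
            index=[f"p{i}" for i in range(5)],
        )
        out = select_degs(res)
        assert list(out.index) == ["p0"]  # each other probe fails exactly one gate
        assert out.loc["p0", "direction"] == 1

    def test_identical_sets_full_retention(self):
        degs = pd.DataFrame(
            dict(log2fc=[1.0, -2.0, 1.5]), index=["a", "b", "c"]
        )
        comp = compare_signatures(degs, degs)
        assert comp.retention_pct == pytest.approx(100.0)
        assert comp.pearson_r == pytest.approx(1.0)

    def test_disjoint_sets_zero_retention(self):
        base = pd.DataFrame(dict(log2fc=[1.0, 2.0]), index=["a", "b"])
        follow = pd.DataFrame(dict(log2fc=[1.0, 2.0]), index=["c", "d"])
        lfc = pd.Series([1.0, 2.0, 0.5, 0.2], index=list("abcd"))
        comp = compare_signatures(base, follow, lfc_base=lfc, lfc_follow=lfc)
        assert comp.retention_pct == 0.0 and comp.n_overlap == 0

    def test_empty_baseline_rejected(self):
        empty = pd.DataFrame(dict(log2fc=[]))
        with pytest.raises(DesignError):
            compare_signatures(empty, empty)

    def test_retention_from_reported_counts(self):
        assert retention_from_counts(926, 717) == 77

    def test_invariants_hold_on_pipeline_output(self, oracle_study):
        _, matrix, meta, _ = oracle_study
        comp, _, _ = signature_stage(matrix, meta)
        assert 0 <= comp.n_overlap <= min(comp.n_base, comp.n_follow)
        assert 0.0 <= comp.retention_pct <= 100.0


class TestVariancePrior:
    def test_homogeneous_variances_give_infinite_prior_df(self):
        s2 = np.full(200, 0.5)
        hyper = fit_variance_prior(s2, df=10.0)
        assert np.isinf(hyper.d0)
        assert hyper.s0_sq > 0
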