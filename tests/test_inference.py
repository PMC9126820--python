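import itertools

import numpy as np
import pytest

from hemisnet import (
    AnalysisConfig,
    SimConfig,
    adjust_pvalues,
    cohens_d_from_t,
    compute_hd,
    compute_metric_panel,
    fit_case_control_model,
    generate_cohort,
    permutation_pvalue,
    run_node_level_analysis,
    run_within_case_models,
)
from hemisnet.inference import _build_design
from hemisnet.lmm import batched_diagnosis_t

from oracles import brute_bh_adjust


class TestHD:
    def test_leftward_positive(self):
        assert compute_hd(10.0, 7.0) == 3.0
        assert compute_hd(5.0, 5.0) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        np.testing.assert_array_equal(compute_hd(a, b), -compute_hd(b, a))

    def test_nonfinite_propagates_as_missing(self):
        hd = compute_hd(np.array([1.0, np.nan]), np.array([0.5, 1.0]))
        assert hd[0] == 0.5 and np.isnan(hd[1])


class TestCohensD:
    def test_direct_arithmetic(self):
        d = cohens_d_from_t(2.0, 50, 50, 96)
        np.testing.assert_allclose(d, 2.0 * 100 / (50 * np.sqrt(96)))
        assert cohens_d_from_t(0.0, 10, 12, 18) == 0.0

    def test_sign_follows_t(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = float(rng.normal())
            d = cohens_d_from_t(t, 13, 17, 26)
            assert np.sign(d) == np.sign(t)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 10, 10, 0)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SimConfig(n_datasets=3, n_cases=10, n_controls=10, rng_seed=21))


class TestPermutation:
    def test_bounds_and_determinism(self, small_cohort):
        table, subjects = small_cohort
        rng = np.random.default_rng(2)
        hd = rng.normal(size=len(subjects))
        p1, t1 = permutation_pvalue(hd, subjects, n_perm=200, rng_seed=9)
        p2, t2 = permutation_pvalue(hd, subjects, n_perm=200, rng_seed=9)
        assert (p1, t1) == (p2, t2)
        assert 1 / 201 <= p1 <= 1.0

    def test_add_one_minimum(self, small_cohort):
        """An outcome perfectly separating the groups beats every
        permutation, giving the smallest attainable p = 1/(n_perm+1)."""
        table, subjects = small_cohort
        diag = np.array([float(s.is_case) for s in subjects])
        rng = np.random.default_rng(3)
        hd = 5.0 * diag + 0.01 * rng.normal(size=len(subjects))
        p, _ = permutation_pvalue(hd, subjects, n_perm=500, rng_seed=1)
        assert p == 1 / 501

    def test_matches_exhaustive_enumeration(self):
        """On a tiny cohort the sampled permutation p converges to the
        exact label-exchange p computed by full enumeration."""
        table, subjects = generate_cohort(
            SimConfig(n_datasets=2, n_cases=2, n_controls=2, rng_seed=31)
        )
        rng = np.random.default_rng(4)
        diag = np.array([float(s.is_case) for s in subjects])
        hd = 0.8 * diag + rng.normal(size=len(subjects))
        des = _build_design(hd, subjects, "main")

        # enumerate all within-dataset label arrangements
        cols = []
        ds = np.asarray(des.groups)
        blocks = [np.flatnonzero(ds == g) for g in np.unique(ds)]
        per_block = [
            list(set(itertools.permutations(des.diag[idx]))) for idx in blocks
        ]
        for combo in itertools.product(*per_block):
            col = np.empty(len(hd))
            for idx, labels in zip(blocks, combo):
                col[idx] = labels
            cols.append(col)
        D = np.stack(cols, axis=1)
        ts = batched_diagnosis_t(des.F, D, des.y, des.groups)
        obs_idx = [i for i in range(D.shape[1]) if np.array_equal(D[:, i], des.diag)]
        t_obs = ts[obs_idx[0]]
        p_exact = np.mean(np.abs(ts) >= np.abs(t_obs) - 1e-12)

        p_hat, _ = permutation_pvalue(hd, subjects, n_perm=4000, rng_seed=8)
        assert abs(p_hat - p_exact) < 0.02

    def test_exact_calibration_for_exchangeable_outcome(self):
        """The label-swap test is exact when the outcome is exchangeable
        within datasets: over replicate iid outcomes on a fixed cohort,
        the 0.05-level rejection rate stays inside the binomial band."""
        from scipy import stats

        table, subjects = generate_cohort(
            SimConfig(n_datasets=5, n_cases=6, n_controls=6, rng_seed=1)
        )
        n_rep = 400
        rejections = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(100_000 + rep)
            hd = rng.normal(size=len(subjects))
            p, _ = permutation_pvalue(hd, subjects, n_perm=500, rng_seed=200_000 + rep)
            rejections += p < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_pipeline_calibrated_with_adequate_control_samples(self):
        """End-to-end calibration of the degree-HD test. The control
        reference is estimated from the cohort's own controls, so the
        label-swap test (which refits only the model) is exact only up
        to reference-estimation noise; with ~24 controls per dataset
        that noise is negligible and the type-I rate is nominal."""
        from scipy import stats

        from hemisnet.regions import DK_REGIONS

        i = DK_REGIONS.index("fusiform")
        n_rep = 50
        rejections = 0
        for rep in range(n_rep):
            table, subjects = generate_cohort(
                SimConfig(n_datasets=5, n_cases=24, n_controls=24, rng_seed=520_000 + rep)
            )
            panel = compute_metric_panel(
                table, subjects, AnalysisConfig(rng_seed=rep),
                node_metrics=("degree_centrality",), hemisphere_level=False,
            )
            hd = panel.node_hd("degree_centrality", i)
            p, _ = permutation_pvalue(
                hd, subjects, n_perm=500, rng_seed=527_777 + rep
            )
            rejections += p < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_within_dataset_preserves_counts(self, small_cohort):
        from hemisnet.inference import _permuted_columns

        table, subjects = small_cohort
        diag = np.array([float(s.is_case) for s in subjects])
        groups = np.array([s.dataset_id for s in subjects])
        D = _permuted_columns(diag, groups, 50, np.random.default_rng(0), True)
        for g in np.unique(groups):
            idx = groups == g
            np.testing.assert_array_equal(D[idx].sum(axis=0), diag[idx].sum())


class TestAdjust:
    def test_hemisphere_bonferroni_threshold(self):
        adj, sig = adjust_pvalues(np.array([0.02, 0.10, 0.04]), "hemisphere")
        assert not sig.any()  # threshold is 0.05/3 ~ 0.0167
        adj, sig = adjust_pvalues(np.array([0.01, 0.10, 0.04]), "hemisphere")
        np.testing.assert_array_equal(sig, [True, False, False])

    def test_bh_hand_example(self):
        p = np.array([0.001, 0.011, 0.02, 0.8])
        adj, _ = adjust_pvalues(p, "edge")
        np.testing.assert_allclose(adj, [0.004, 0.022, 4 * 0.02 / 3, 0.8])

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.0005, 1, size=34)
        adj, _ = adjust_pvalues(p, "node")
        np.testing.assert_allclose(adj, brute_bh_adjust(p), rtol=1e-12)

    def test_bh_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1, size=34)
        adj, sig = adjust_pvalues(p, "node")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # a significant p is never larger than a non-significant one
        if sig.any() and (~sig).any():
            assert p[sig].max() <= p[~sig].min()

    def test_all_ones_never_significant(self):
        adj, sig = adjust_pvalues(np.ones(34), "node")
        assert not sig.any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adjust_pvalues(np.array([]), "node")


class TestCaseControlModel:
    def test_noise_free_recovery(self, small_cohort):
        table, subjects = small_cohort
        hd = np.array([0.5 if s.is_case else 0.0 for s in subjects])
        coef, t, df = fit_case_control_model(hd, subjects)
        np.testing.assert_allclose(coef, 0.5, atol=1e-8)

    def test_missing_age_excluded_not_fatal(self, small_cohort):
        table, subjects = small_cohort
        import dataclasses

        subjects2 = [dataclasses.replace(s) for s in subjects]
        subjects2[0].age = float("nan")
        rng = np.random.default_rng(7)
        hd = rng.normal(size=len(subjects2))
        des = _build_design(hd, subjects2, "main")
        assert len(des.y) == len(subjects2) - 1

    def test_one_group_missing_rejected(self, small_cohort):
        table, subjects = small_cohort
        controls = [s for s in subjects if not s.is_case]
        hd = np.arange(len(controls), dtype=float)
        with pytest.raises(ValueError, match="groups"):
            fit_case_control_model(hd, controls)


def test_main_analysis_result_count(tiny_cohort):
    """4 node metrics x 34 regions + 3 hemisphere metrics = 139 tests."""
    table, subjects = tiny_cohort
    cfg = AnalysisConfig(n_permutations=19, n_null_networks=2, rng_seed=1)
    results = run_node_level_analysis(
        table, subjects, cfg, follow_up_unilateral=False
    )
    assert len(results) == 139
    assert sum(r.tier == "hemisphere" for r in results) == 3
    assert sum(r.tier == "node" for r in results) == 136
    for r in results:
        assert r.p_adjusted is not None and r.significant is not None
        assert 1 / 20 <= r.p_empirical <= 1


class TestWithinCase:
    def test_ados_association_recovered(self):
        """HD built as 0.1 * ADOS + noise yields a positive coefficient."""
        table, subjects = generate_cohort(
            SimConfig(n_datasets=3, n_cases=40, n_controls=10, rng_seed=41)
        )
        cfg = AnalysisConfig(n_permutations=199, rng_seed=3)
        panel = compute_metric_panel(
            table, subjects, cfg,
            node_metrics=("degree_centrality",), hemisphere_level=False,
        )
        rng = np.random.default_rng(9)
        cases = [s for s in subjects if s.is_case]
        fake_hd = np.array(
            [0.1 * s.ados_total for s in cases]
        ) + 0.2 * rng.normal(size=len(cases))
        # plant the HD into the panel for one region
        full = np.zeros(len(subjects))
        full[[i for i, s in enumerate(subjects) if s.is_case]] = fake_hd
        panel.node_values["degree_centrality"]["L"][:, 0] = full
        panel.node_values["degree_centrality"]["R"][:, 0] = 0.0
        from hemisnet import TestResult

        target = TestResult(
            tier="node", metric="degree_centrality", node="bankssts",
            n_cases=120, n_controls=30, coefficient=0.0, t=0.0,
            cohens_d=0.0, p_empirical=0.5, significant=True,
        )
        results, skipped = run_within_case_models(
            panel, subjects, cfg, [target], variables=("ados",)
        )
        assert len(results) == 1
        assert results[0].coefficient > 0.05
        assert results[0].p_empirical < 0.05

    def test_all_missing_variable_skipped(self, tiny_cohort):
        table, subjects = tiny_cohort
        import dataclasses

        subjects2 = [dataclasses.replace(s, iq=None) for s in subjects]
        cfg = AnalysisConfig(n_permutations=19, rng_seed=5)
        panel = compute_metric_panel(
            table, subjects2, cfg,
            node_metrics=("degree_centrality",), hemisphere_level=False,
        )
        from hemisnet import TestResult

        target = TestResult(
            tier="node", metric="degree_centrality", node="fusiform",
            n_cases=6, n_controls=6, coefficient=0.0, t=0.0,
            cohens_d=0.0, p_empirical=0.5, significant=True,
        )
        results, skipped = run_within_case_models(
            panel, subjects2, cfg, [target], variables=("iq",)
        )
        assert results == []
        assert len(skipped) == 1 and "iq" in skipped[0]
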