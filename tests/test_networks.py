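import itertools

import numpy as np
import pandas as pd
import pytest

from hemisnet import (
    binarize_by_sparsity,
    build_weighted_network,
    build_weighted_networks,
    compute_control_reference,
    retained_edges,
    standardize,
)
from hemisnet.networks import gaussian_similarity, triu_pairs
from hemisnet.regions import N_EDGES, N_REGIONS
from hemisnet.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SimConfig(n_datasets=2, n_cases=4, n_controls=5, rng_seed=2))


class TestControlReference:
    def test_hand_arithmetic(self, cohort):
        table, subjects = cohort
        frame = table.data.copy()
        ds = subjects[0].dataset_id
        controls = [s.subject_id for s in subjects if not s.is_case and s.dataset_id == ds]
        # plant known control values in one region
        frame.loc[controls[:3], "fusiform_L"] = [2.0, 2.5, 3.0]
        frame.loc[controls[3:], "fusiform_L"] = 2.5  # keep mean unchanged
        from hemisnet import ThicknessTable

        ref = compute_control_reference(ThicknessTable(frame), subjects)
        np.testing.assert_allclose(ref.means.loc[ds, "fusiform_L"], 2.5)
        expected_sd = np.std([2.0, 2.5, 3.0, 2.5, 2.5], ddof=1)
        np.testing.assert_allclose(ref.sds.loc[ds, "fusiform_L"], expected_sd)

    def test_constant_region_rejected(self, cohort):
        table, subjects = cohort
        frame = table.data.copy()
        controls = [s.subject_id for s in subjects if not s.is_case]
        frame.loc[controls, "cuneus_R"] = 2.2
        from hemisnet import ThicknessTable

        with pytest.raises(ValueError, match="cuneus_R"):
            compute_control_reference(ThicknessTable(frame), subjects)

    def test_cases_do_not_affect_reference(self, cohort):
        table, subjects = cohort
        ref = compute_control_reference(table, subjects)
        frame = table.data.copy()
        cases = [s.subject_id for s in subjects if s.is_case]
        frame.loc[cases] = frame.loc[cases] * 1.5
        from hemisnet import ThicknessTable

        ref2 = compute_control_reference(ThicknessTable(frame), subjects)
        pd.testing.assert_frame_equal(ref.means, ref2.means)
        pd.testing.assert_frame_equal(ref.sds, ref2.sds)


class TestStandardize:
    def test_direct_formula(self, cohort):
        table, subjects = cohort
        ref = compute_control_reference(table, subjects)
        z = standardize(table, subjects, ref)
        s0 = subjects[0]
        m, sd = ref.for_dataset(s0.dataset_id)
        expected = (table.data.loc[s0.subject_id].to_numpy() - m) / sd
        np.testing.assert_allclose(z.loc[s0.subject_id].to_numpy(), expected)

    def test_controls_standardize_to_unit(self, cohort):
        """Within a dataset, control z-values have mean 0 and sample SD 1."""
        table, subjects = cohort
        ref = compute_control_reference(table, subjects)
        z = standardize(table, subjects, ref)
        ds = subjects[0].dataset_id
        controls = [s.subject_id for s in subjects if not s.is_case and s.dataset_id == ds]
        sub = z.loc[controls]
        np.testing.assert_allclose(sub.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sub.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_unknown_dataset_rejected(self, cohort):
        table, subjects = cohort
        ref = compute_control_reference(table, subjects)
        bad = [
            type(s)(
                subject_id=s.subject_id, dataset_id="nowhere",
                diagnosis=s.diagnosis, age=s.age, sex=s.sex,
            )
            for s in subjects
        ]
        with pytest.raises(KeyError, match="nowhere"):
            standardize(table, bad, ref)


class TestWeightedNetwork:
    def test_kernel_values(self):
        z = np.zeros(N_REGIONS)
        z[1] = 2.0  # |z0 - z1| = 2
        w = build_weighted_network(z)
        np.testing.assert_allclose(w[0, 2], 1.0)  # identical z -> weight 1
        np.testing.assert_allclose(w[0, 1], np.exp(-2.0))
        assert np.all(np.diag(w) == 0)
        np.testing.assert_array_equal(w, w.T)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=N_REGIONS)
        perm = rng.permutation(N_REGIONS)
        w = build_weighted_network(z)
        w_perm = build_weighted_network(z[perm])
        np.testing.assert_allclose(w_perm, w[np.ix_(perm, perm)])

    def test_nonfinite_rejected(self):
        z = np.zeros(N_REGIONS)
        z[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            build_weighted_network(z)

    def test_batch_matches_single(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(5, N_REGIONS))
        stack = build_weighted_networks(z)
        for i in range(5):
            np.testing.assert_allclose(stack[i], build_weighted_network(z[i]))


class TestBinarize:
    def test_edge_counts(self):
        assert N_EDGES == 561
        assert retained_edges(0.4) == 224
        rng = np.random.default_rng(1)
        w = build_weighted_network(rng.normal(size=N_REGIONS))
        b = binarize_by_sparsity(w, 0.4)
        assert int(np.triu(b, k=1).sum()) == 224

    @pytest.mark.parametrize("sparsity", [0.25, 0.31, 0.4, 0.5, 1.0])
    def test_edge_count_conservation(self, sparsity):
        rng = np.random.default_rng(2)
        w = build_weighted_networks(rng.normal(size=(6, N_REGIONS)))
        b = binarize_by_sparsity(w, sparsity)
        m = retained_edges(sparsity)
        for i in range(6):
            assert int(np.triu(b[i], k=1).sum()) == m

    def test_all_equal_weights_still_exact_count(self):
        w = np.ones((N_REGIONS, N_REGIONS)) * 0.5
        np.fill_diagonal(w, 0.0)
        b = binarize_by_sparsity(w, 0.4)
        assert int(np.triu(b, k=1).sum()) == 224
        # deterministic: lexicographically first pairs retained
        iu, ju = triu_pairs()
        kept = np.flatnonzero(b[iu, ju])
        np.testing.assert_array_equal(kept, np.arange(224))

    def test_five_node_toy_against_exhaustive_sort(self):
        """Distinct weights on 10 pairs; the top-4 pairs must be kept."""
        n = 5
        rng = np.random.default_rng(3)
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        vals = rng.permutation(np.linspace(0.0, 0.9, len(iu)))
        w[iu, ju] = vals
        w = w + w.T
        b = binarize_by_sparsity(w, 0.4)
        m = int(np.floor(0.4 * len(iu)))
        pairs = sorted(zip(vals, iu, ju), reverse=True)[:m]
        expected = np.zeros((n, n))
        for _, i, j in pairs:
            expected[i, j] = expected[j, i] = 1
        np.testing.assert_array_equal(b, expected)

    def test_sparsity_bounds(self):
        w = np.zeros((N_REGIONS, N_REGIONS))
        with pytest.raises(ValueError):
            binarize_by_sparsity(w, 0.0)
        with pytest.raises(ValueError):
            binarize_by_sparsity(w, 1.1)

    def test_monotone_kernel_invariance(self):
        """Binarized topology is identical under any strictly decreasing
        kernel of |z_i - z_j| — thresholding sees only the ranks."""
        rng = np.random.default_rng(6)
        z = rng.normal(size=(10, N_REGIONS))
        b1 = binarize_by_sparsity(build_weighted_networks(z, gaussian_similarity), 0.4)
        b2 = binarize_by_sparsity(
            build_weighted_networks(z, lambda d: 1.0 / (1.0 + d)), 0.4
        )
        np.testing.assert_array_equal(b1, b2)


def test_hemisphere_swap_symmetry(cohort):
    """Swapping hemisphere labels in the input swaps the output networks."""
    table, subjects = cohort
    ref = compute_control_reference(table, subjects)
    z = standardize(table, subjects, ref)
    from hemisnet.regions import hemisphere_columns

    wl = build_weighted_networks(z[hemisphere_columns("L")].to_numpy())
    swapped = table.swap_hemispheres()
    ref_s = compute_control_reference(swapped, subjects)
    z_s = standardize(swapped, subjects, ref_s)
    wr_s = build_weighted_networks(z_s[hemisphere_columns("R")].to_numpy())
    np.testing.assert_allclose(wl, wr_s)
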