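"""Synthetic-generator contracts: determinism, non-negativity, planted
structure, hierarchy, subgroups, nulls, and tabular round-trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opnmfkit import (
    DKEFS_ITEMS,
    adjusted_rand_index,
    generate_basis,
    generate_hierarchical,
    generate_null,
    generate_scores,
    generate_subgroups,
    load_scores,
    opnmf_fit,
    parallel_analysis,
    reconstruction_error,
)


class TestGenerateBasis:
    def test_disjoint_blocks_for_zero_overlap(self):
        B = generate_basis(p=4, k=2, overlap=0.0, seed=0)
        assert np.all(B[:2, 1] == 0) and np.all(B[2:, 0] == 0)
        assert np.all(B[:2, 0] > 0) and np.all(B[2:, 1] > 0)

    def test_seed_determinism(self):
        a = generate_basis(17, 2, overlap=0.0, seed=1)
        b = generate_basis(17, 2, overlap=0.0, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_overlap_keeps_argmax_on_home_factor(self):
        B = generate_basis(17, 5, overlap=0.2, seed=7)
        home = np.repeat(np.arange(5), [4, 4, 3, 3, 3])
        np.testing.assert_array_equal(np.argmax(B, axis=1), home)
        # secondary loadings exist but stay subordinate
        assert np.any(np.sum(B > 0, axis=1) > 1)

    def test_unit_column_norms(self):
        B = generate_basis(17, 3, overlap=0.3, seed=2)
        np.testing.assert_allclose(np.linalg.norm(B, axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(p=4, k=5), dict(p=4, k=2, overlap=1.0),
                                     dict(p=4, k=2, overlap=-0.1)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            generate_basis(**bad)


class TestGenerateScores:
    def test_noiseless_product_identity_and_opnmf_recovery(self):
        sm, truth = generate_scores(p=17, k=2, n=200, noise_sd=0.0, seed=5)
        np.testing.assert_allclose(sm.values, truth.basis_true @ truth.scores_true)
        sol = opnmf_fit(sm, 2, tol=1e-10, max_iter=100_000)
        assert reconstruction_error(sm, sol.basis) < 1e-6

    def test_all_entries_non_negative_under_noise(self):
        sm, _ = generate_scores(p=17, k=2, n=334, noise_sd=0.25, seed=42)
        assert np.all(sm.values >= 0)

    def test_noiseless_two_factor_sample_has_rank_two_eigenstructure(self):
        sm, _ = generate_scores(p=17, k=2, n=5000, noise_sd=0.0, seed=8)
        evals = np.sort(np.linalg.eigvalsh(np.cov(sm.values)))[::-1]
        assert evals[1] > 1e-3
        assert evals[2] < 1e-8 * evals[0]

    def test_default_item_labels_are_the_battery_variables(self):
        sm, _ = generate_scores(p=17, k=2, n=10, seed=0)
        assert tuple(sm.item_labels) == DKEFS_ITEMS

    def test_skew_flag_changes_marginals_and_is_recorded(self):
        sm, truth = generate_scores(p=17, k=2, n=2000, noise_sd=0.0, skew=True, seed=3)
        assert "lognormal" in truth.metadata["score_distribution"]
        base, _ = generate_scores(p=17, k=2, n=2000, noise_sd=0.0, skew=False, seed=3)
        assert sm.values.max() > base.values.max()  # heavier right tail

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_scores(noise_sd=-0.1)


class TestGenerateHierarchical:
    def test_partition_counts_and_nesting_consistency(self):
        sm, truth = generate_hierarchical(
            p=17, k_fine=5, k_coarse=2, within_corr=0.7, n=334, seed=3
        )
        assert len(np.unique(truth.partition_true)) == 5
        assert len(np.unique(truth.partition_coarse)) == 2
        merged = truth.nesting[truth.partition_true]
        assert adjusted_rand_index(merged, truth.partition_coarse) == 1.0

    def test_within_coarse_correlations_exceed_between(self):
        sm, truth = generate_hierarchical(
            p=17, k_fine=5, k_coarse=2, within_corr=0.7, n=8000, noise_sd=0.1, seed=11
        )
        R = np.corrcoef(sm.values)
        coarse = truth.partition_coarse
        same = R[np.equal.outer(coarse, coarse) & ~np.eye(17, dtype=bool)]
        diff = R[~np.equal.outer(coarse, coarse)]
        assert same.mean() > diff.mean()

    def test_invalid_within_corr(self):
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                generate_hierarchical(within_corr=bad)


class TestGenerateSubgroups:
    def test_shared_basis_and_sizes(self):
        sm, truth = generate_subgroups(
            [("M", 101, 0.0), ("F", 233, 0.0)], p=17, k=2, noise_sd=0.0, seed=1
        )
        assert sm.n_subjects == 334
        labels = [sm.group_labels[s] for s in sm.subject_ids]
        assert labels.count("M") == 101 and labels.count("F") == 233

    def test_arbitrary_sizes_supported(self):
        sm, _ = generate_subgroups(
            [("old", 144, 0.0), ("young", 220, 0.0)], p=17, k=2, seed=0
        )
        assert sm.n_subjects == 364

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            generate_subgroups([("A", 10, 0.0), ("A", 10, 0.0)])

    def test_unperturbed_groups_share_correlation_structure(self):
        sm, _ = generate_subgroups(
            [("a", 2500, 0.0), ("b", 2500, 0.0)], p=8, k=2, noise_sd=0.2, seed=9
        )
        ids = np.asarray([sm.group_labels[s] for s in sm.subject_ids])
        Ra = np.corrcoef(sm.values[:, ids == "a"])
        Rb = np.corrcoef(sm.values[:, ids == "b"])
        assert np.max(np.abs(Ra - Rb)) < 0.12  # sampling error only


class TestGenerateNull:
    def test_seed_determinism(self):
        np.testing.assert_array_equal(
            generate_null(17, 334, seed=5).values, generate_null(17, 334, seed=5).values
        )

    def test_mean_off_diagonal_correlation_near_zero(self):
        sm = generate_null(p=17, n=334, seed=5)
        R = np.corrcoef(sm.values)
        off = R[~np.eye(17, dtype=bool)]
        assert abs(off.mean()) < 3 / np.sqrt(334)

    def test_parallel_analysis_retains_nothing_usually(self):
        hits = sum(
            parallel_analysis(generate_null(17, 334, seed=s), n_sim=100, seed=1000 + s).k_parallel
            == 0
            for s in range(20)
        )
        assert hits >= 18


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.sampled_from([0.0, 0.1, 0.3]))
def test_generated_matrices_are_non_negative_and_deterministic(seed, noise_sd):
    a, _ = generate_scores(p=8, k=2, n=30, noise_sd=noise_sd, seed=seed)
    b, _ = generate_scores(p=8, k=2, n=30, noise_sd=noise_sd, seed=seed)
    assert np.all(a.values >= 0)
    np.testing.assert_array_equal(a.values, b.values)


def test_csv_round_trip_with_ground_truth_sidecar(tmp_path):
    sm, truth = generate_subgroups(
        [("M", 10, 0.0), ("F", 12, 0.0)], p=6, k=2, noise_sd=0.1, seed=4
    )
    path = tmp_path / "scores.csv"
    sm.write_csv(path)
    truth.write_json(tmp_path / "truth.json")
    back = load_scores(path)
    np.testing.assert_array_equal(back.values, sm.values)
    assert back.item_labels == sm.item_labels
    assert back.group_labels == sm.group_labels
    with open(tmp_path / "truth.json") as fh:
        stored = json.load(fh)
    np.testing.assert_allclose(np.asarray(stored["basis_true"]), truth.basis_true)
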