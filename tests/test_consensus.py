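import itertools

import numpy as np
import pandas as pd
import pytest

from trajconsensus.consensus import (
    build_consensus_matrix,
    final_hierarchical_partition,
    longitudinal_consensus_cluster,
    merge_consensus,
    save_consensus,
)
from trajconsensus.diagnostics import rand_index
from trajconsensus.io_model import ConfigurationError, LongitudinalDataset

from conftest import make_two_group_scores


class TestBuildConsensusMatrix:
    def test_single_run_single_cluster_all_ones(self):
        subjects = ["a", "b", "c"]
        M, N, warnings = build_consensus_matrix([(subjects, [1, 1, 1])], subjects)
        np.testing.assert_allclose(M, 1.0)
        np.testing.assert_allclose(N, 1.0)
        assert warnings == []

    def test_three_run_fixture_exact_fractions(self):
        # oracle: explicit pair counting over the 3 runs
        # runs: AB|C, AB|C, A|BC with full sampling
        subjects = ["A", "B", "C"]
        runs = [
            (subjects, [1, 1, 2]),
            (subjects, [1, 1, 2]),
            (subjects, [1, 2, 2]),
        ]
        M, N, _ = build_consensus_matrix(runs, subjects)
        assert M[0, 1] == pytest.approx(2 / 3)
        assert M[1, 2] == pytest.approx(1 / 3)
        assert M[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(N, 3.0)
        np.testing.assert_allclose(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)

    def test_never_sampled_subject_zero_row_and_warning(self):
        subjects = ["a", "b", "c"]
        M, N, warnings = build_consensus_matrix([(["a", "b"], [1, 2])], subjects)
        np.testing.assert_allclose(M[2], 0.0)
        np.testing.assert_allclose(N[2], 0.0)
        assert len(warnings) == 1 and "never co-sampled" in warnings[0]

    def test_count_product_is_integer_run_count(self):
        subjects = list("abcde")
        rng = np.random.default_rng(0)
        runs = []
        for _ in range(7):
            chosen = sorted(rng.choice(5, size=4, replace=False))
            labels = rng.integers(1, 3, size=4)
            runs.append(([subjects[i] for i in chosen], labels))
        M, N, _ = build_consensus_matrix(runs, subjects)
        prod = M * N
        np.testing.assert_allclose(prod, np.round(prod), atol=1e-9)
        assert np.all(prod <= 7)

    def test_labels_for_unknown_subject_rejected(self):
        with pytest.raises(ConfigurationError):
            build_consensus_matrix([(["a", "z"], [1, 2])], ["a", "b"])


class TestFinalPartition:
    def test_binary_block_diagonal_recovered(self):
        M = np.zeros((6, 6))
        M[:3, :3] = 1.0
        M[3:, 3:] = 1.0
        labels, Z = final_hierarchical_partition(M, 2)
        assert rand_index(labels, [1, 1, 1, 2, 2, 2]) == 1.0

    def test_soft_blocks_match_brute_force_oracle(self):
        # oracle: best 2-partition by within-minus-between mean consensus,
        # found by enumerating all 2-partitions of 6 subjects
        M = np.full((6, 6), 0.1)
        M[:3, :3] = 0.9
        M[3:, 3:] = 0.9
        np.fill_diagonal(M, 1.0)

        def score(partition):
            within, between = [], []
            for i, j in itertools.combinations(range(6), 2):
                (within if partition[i] == partition[j] else between).append(M[i, j])
            w = np.mean(within) if within else 0.0
            b = np.mean(between) if between else 0.0
            return w - b

        best = max(
            (tuple(p) for p in itertools.product([0, 1], repeat=6)
             if 0 < sum(p) < 6),
            key=score,
        )
        labels, _ = final_hierarchical_partition(M, 2)
        assert rand_index(labels, list(best)) == 1.0

    def test_all_disconnected_gives_deterministic_cut(self):
        M = np.eye(4)
        labels1, _ = final_hierarchical_partition(M, 2)
        labels2, _ = final_hierarchical_partition(M, 2)
        np.testing.assert_array_equal(labels1, labels2)

    def test_k_above_n_rejected(self):
        with pytest.raises(ConfigurationError):
            final_hierarchical_partition(np.eye(3), 4)


class TestLongitudinalConsensus:
    def test_separated_groups_binary_matrix_and_exact_recovery(self):
        ds, truth = make_two_group_scores(n_subjects=14, noise_sd=0.01, seed=2)
        result = longitudinal_consensus_cluster(
            ds, [2], reps=8, df=2, seed=0, variance_floor=1e-6
        )
        kc = result.by_K[2]
        off = kc.matrix[np.triu_indices(14, 1)]
        assert set(np.round(off, 8)).issubset({0.0, 1.0})
        assert rand_index(kc.final_labels.to_numpy(), truth) == 1.0

    def test_full_sampling_single_rep_equals_co_membership(self):
        ds, _ = make_two_group_scores(n_subjects=10, noise_sd=0.05, seed=3)
        result = longitudinal_consensus_cluster(
            ds, [2], reps=1, subsample_fraction=1.0, df=2, seed=1
        )
        kc = result.by_K[2]
        labels = kc.runs[0]["labels"]
        co = (np.asarray(labels)[:, None] == np.asarray(labels)[None, :]).astype(float)
        np.testing.assert_allclose(kc.matrix, co)

    def test_k_exceeding_subsample_rejected(self):
        ds, _ = make_two_group_scores(n_subjects=6)
        with pytest.raises(ConfigurationError, match="subsample"):
            longitudinal_consensus_cluster(ds, [6], reps=2, subsample_fraction=0.8)

    def test_fixed_seed_bit_reproducible(self):
        ds, _ = make_two_group_scores(n_subjects=12, noise_sd=0.2, seed=4)
        r1 = longitudinal_consensus_cluster(ds, [2, 3], reps=4, df=2, seed=9)
        r2 = longitudinal_consensus_cluster(ds, [2, 3], reps=4, df=2, seed=9)
        for K in (2, 3):
            np.testing.assert_array_equal(r1.by_K[K].matrix, r2.by_K[K].matrix)
            np.testing.assert_array_equal(
                r1.by_K[K].final_labels.to_numpy(), r2.by_K[K].final_labels.to_numpy()
            )

    def test_subject_permutation_permutes_matrix(self):
        ds, _ = make_two_group_scores(n_subjects=10, noise_sd=0.2, seed=5)
        result = longitudinal_consensus_cluster(
            ds, [2], reps=1, subsample_fraction=1.0, df=2, seed=2
        )
        subjects = ds.subjects
        order = np.random.default_rng(1).permutation(len(subjects))
        frames = [ds.data[ds.data[ds.id_col] == subjects[i]] for i in order]
        permuted_ds = LongitudinalDataset(
            pd.concat(frames, ignore_index=True), ds.id_col, ds.time_col, ds.variables
        )
        result_p = longitudinal_consensus_cluster(
            permuted_ds, [2], reps=1, subsample_fraction=1.0, df=2, seed=2
        )
        M = result.by_K[2].matrix
        np.testing.assert_allclose(result_p.by_K[2].matrix, M[np.ix_(order, order)])
        # final clusters identical as subject sets
        a = result.by_K[2].final_labels
        b = result_p.by_K[2].final_labels
        assert rand_index(a, b) == 1.0

    def test_batch_merge_equals_single_batch(self):
        ds, _ = make_two_group_scores(n_subjects=12, noise_sd=0.3, seed=6)
        full = longitudinal_consensus_cluster(ds, [2], reps=5, df=2, seed=11)
        first = longitudinal_consensus_cluster(ds, [2], reps=3, df=2, seed=11)
        second = longitudinal_consensus_cluster(
            ds, [2], reps=2, df=2, seed=11, rep_offset=3
        )
        merged = merge_consensus(first, second)
        np.testing.assert_allclose(merged.by_K[2].matrix, full.by_K[2].matrix, atol=1e-12)
        np.testing.assert_array_equal(merged.by_K[2].counts, full.by_K[2].counts)

    def test_serialization_layout(self, tmp_path):
        ds, _ = make_two_group_scores(n_subjects=8, noise_sd=0.2, seed=7)
        result = longitudinal_consensus_cluster(ds, [2], reps=2, df=2, seed=0)
        out = tmp_path / "cc"
        save_consensus(result, out)
        assert (out / "settings.json").exists()
        assert (out / "consensus_K2.csv").exists()
        assert (out / "labels.csv").exists()
        assert (out / "runs.jsonl").exists()
        mat = pd.read_csv(out / "consensus_K2.csv", index_col=0)
        np.testing.assert_allclose(mat.to_numpy(), result.by_K[2].matrix)
        assert list(mat.index) == [str(s) for s in result.subjects]
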