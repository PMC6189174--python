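"""Clustering determinism, consensus construction, k selection and group scores."""

import numpy as np
import pandas as pd
import pytest

from glandscape import consensus_cluster as cc
from glandscape.errors import UnitError
from glandscape.matrix_io import ExpressionMatrix


def expr_from_array(values, unit="log2TPM"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"c{j}" for j in range(values.shape[1])],
        ),
        unit,
    )


def two_clouds(n_per=15, seed=0):
    """Two cell clouds with distinct rank profiles over 40 genes."""
    rng = np.random.default_rng(seed)
    base_a = rng.permutation(40).astype(float)
    base_b = rng.permutation(40).astype(float)
    cells = np.column_stack(
        [base_a + rng.normal(0, 1.0, 40) for _ in range(n_per)]
        + [base_b + rng.normal(0, 1.0, 40) for _ in range(n_per)]
    )
    return expr_from_array(np.abs(cells)), np.array([0] * n_per + [1] * n_per)


def labels_from_list(values):
    return cc.ClusterLabels(
        labels=pd.Series(values, index=[f"c{j}" for j in range(len(values))]),
        k=len(set(values)),
    )


class TestClusterCells:
    def test_separable_clouds_recovered_exactly(self):
        expr, truth = two_clouds()
        got = cc.cluster_cells(expr, 2).labels.to_numpy()
        # first-appearance labelling makes truth's own labelling canonical
        assert np.array_equal(got, truth)

    def test_k_one_is_single_cluster(self):
        expr, _ = two_clouds()
        assert set(cc.cluster_cells(expr, 1).labels) == {0}

    def test_duplicated_columns_always_co_cluster(self):
        rng = np.random.default_rng(3)
        col = rng.random(30)
        arr = np.column_stack([col, col, rng.random(30), rng.random(30), col])
        expr = expr_from_array(arr)
        lab = cc.cluster_cells(expr, 3).labels
        assert lab.iloc[0] == lab.iloc[1] == lab.iloc[4]

    def test_k_above_n_cells_rejected(self):
        expr, _ = two_clouds(n_per=3)
        with pytest.raises(ValueError):
            cc.cluster_cells(expr, 7)

    def test_requires_log2tpm_unit(self):
        expr, _ = two_clouds()
        with pytest.raises(UnitError):
            cc.cluster_cells(ExpressionMatrix(expr.values, "TPM"), 2)


class TestConsensusFromLabels:
    def test_identical_labelings_give_binary_consensus(self):
        labs = [labels_from_list([0, 0, 1, 1])] * 3
        c = cc.consensus_from_labels(labs).matrix.to_numpy()
        assert set(np.unique(c)) <= {0.0, 1.0}

    def test_half_agreement_gives_half_frequency(self):
        labs = [labels_from_list([0, 0, 1]), labels_from_list([0, 1, 1])]
        c = cc.consensus_from_labels(labs).matrix
        assert c.loc["c0", "c1"] == 0.5

    def test_invariants_on_random_labelings(self):
        rng = np.random.default_rng(11)
        labs = [labels_from_list(rng.integers(0, 4, 30).tolist()) for _ in range(10)]
        c = cc.consensus_from_labels(labs).matrix.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert c.min() >= 0 and c.max() <= 1

    def test_mismatched_cell_sets_rejected(self):
        a = labels_from_list([0, 1])
        b = cc.ClusterLabels(labels=pd.Series([0, 1], index=["x", "y"]), k=2)
        with pytest.raises(ValueError):
            cc.consensus_from_labels([a, b])


class TestChooseK:
    def test_singleton_cluster_silhouette_is_zero(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        values = cc._cluster_silhouettes(d, np.array([0, 0, 1]))
        assert values[1] == 0.0  # the singleton

    def test_empty_k_range_rejected(self, filtered_plate, noise_model):
        from glandscape import noise_replicates as nr

        reps = nr.simulate_replicates(filtered_plate, noise_model, 2, seed=1)
        with pytest.raises(ValueError):
            cc.choose_k(reps, [])

    def test_homogeneous_cloud_has_low_silhouettes(self):
        """Single population: pooled medians stay below 0.25 for every k."""
        from conftest import make_matrix
        from glandscape import noise_replicates as nr
        from glandscape import synthdata as sd

        panel = sd.build_panel(60, 8, seed=5)
        design = sd.CellDesign([sd.GroupDesign("only", 80)], size_factor_sd=0.2)
        m = sd.simulate_counts(panel, design, sd.NoiseParams(), seed=5)
        model = nr.fit_noise_model(m)
        reps = nr.simulate_replicates(m, model, 10, seed=5)
        ksel = cc.choose_k(reps, range(2, 6))
        for values in ksel.silhouettes.values():
            assert np.median(values) < 0.25


class TestFinalClusters:
    def _block_consensus(self, sizes, within=1.0, between=0.0):
        n = sum(sizes)
        c = np.full((n, n), between)
        start = 0
        for s in sizes:
            c[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(c, 1.0)
        cells = [f"c{j}" for j in range(n)]
        return cc.ConsensusMatrix(pd.DataFrame(c, index=cells, columns=cells))

    def test_binary_blocks_recovered(self):
        cons = self._block_consensus([4, 3, 5])
        lab = cc.final_clusters(cons, 3).labels.to_numpy()
        assert np.array_equal(lab, [0] * 4 + [1] * 3 + [2] * 5)

    def test_noisy_blocks_recovered(self):
        cons = self._block_consensus([6, 6, 6], within=0.9, between=0.1)
        lab = cc.final_clusters(cons, 3).labels.to_numpy()
        assert np.array_equal(lab, [0] * 6 + [1] * 6 + [2] * 6)

    def test_all_ones_consensus_handled_deterministically(self):
        cons = self._block_consensus([6], within=1.0)
        assert set(cc.final_clusters(cons, 1).labels) == {0}
        a = cc.final_clusters(cons, 2).labels
        b = cc.final_clusters(cons, 2).labels
        assert a.equals(b)


class TestGroupScore:
    def _block_consensus(self, sizes, within=1.0, between=0.0):
        return TestFinalClusters._block_consensus(self, sizes, within, between)

    def test_perfect_blocks_score_one(self):
        cons = self._block_consensus([5, 5])
        groups = {f"c{j}": ("A" if j < 5 else "B") for j in range(10)}
        gs = cc.group_score(cons, groups)
        assert np.allclose(gs.per_group["score"], 1.0)
        assert gs.mean_score == pytest.approx(1.0)

    def test_random_groups_score_near_zero(self):
        """Groups drawn independently of block structure: E[score] = 0."""
        cons = self._block_consensus([100, 100], within=0.95, between=0.05)
        rng = np.random.default_rng(23)
        scores = []
        for _ in range(50):
            perm = rng.permutation(200)
            groups = {f"c{j}": ("A" if i < 100 else "B") for i, j in enumerate(perm)}
            scores.append(cc.group_score(cons, groups).mean_score)
        assert abs(np.mean(scores)) < 0.1

    def test_hand_computed_four_cell_fixture(self):
        c = np.array(
            [
                [1.0, 0.8, 0.2, 0.0],
                [0.8, 1.0, 0.4, 0.2],
                [0.2, 0.4, 1.0, 0.6],
                [0.0, 0.2, 0.6, 1.0],
            ]
        )
        cells = ["c0", "c1", "c2", "c3"]
        cons = cc.ConsensusMatrix(pd.DataFrame(c, index=cells, columns=cells))
        gs = cc.group_score(cons, {"c0": "A", "c1": "A", "c2": "B", "c3": "B"})
        a = gs.per_group.loc["A"]
        # stability(A) = 0.8; promiscuity(A) = mean(0.2, 0.0, 0.4, 0.2) = 0.2
        assert a["stability"] == pytest.approx(0.8)
        assert a["promiscuity"] == pytest.approx(0.2)
        assert a["score"] == pytest.approx(0.6)
        b = gs.per_group.loc["B"]
        assert b["stability"] == pytest.approx(0.6)
        # promiscuity(B) = mean(0.2, 0.4, 0.0, 0.2) = 0.2
        assert b["score"] == pytest.approx(0.6 - 0.2)

    def test_ensemble_single_group_has_zero_promiscuity(self):
        cons = self._block_consensus([4, 4], within=0.9, between=0.1)
        groups = {f"c{j}": "ensemble" for j in range(8)}
        gs = cc.group_score(cons, groups)
        assert gs.per_group.loc["ensemble", "promiscuity"] == 0.0

    def test_undersized_group_rejected(self):
        cons = self._block_consensus([3, 2])
        groups = {"c0": "A", "c1": "A", "c2": "A", "c3": "A", "c4": "B"}
        with pytest.raises(ValueError):
            cc.group_score(cons, groups)

    def test_score_decreases_under_group_mixing(self):
        """Swapping members between well-separated groups degrades the score."""
        cons = self._block_consensus([50, 50], within=0.95, between=0.05)
        def mixed_score(f):
            n_swap = int(f * 50)
            names = {}
            for j in range(100):
                grp = "A" if j < 50 else "B"
                if j < n_swap or 50 <= j < 50 + n_swap:
                    grp = "B" if grp == "A" else "A"
                names[f"c{j}"] = grp
            return cc.group_score(cons, names).mean_score
        s0, s1, s3 = mixed_score(0.0), mixed_score(0.1), mixed_score(0.3)
        assert s0 > s1 > s3
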