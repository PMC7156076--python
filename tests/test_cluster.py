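"""Binary distances, deterministic hierarchical clustering, detection maps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import detectome as dt
import detectome.cluster as dc
from detectome.model import DetectomeError
from conftest import random_call_matrix


def naive_average_linkage_cophenetic(dist: pd.DataFrame) -> pd.DataFrame:
    """O(n^3) reference agglomerative clustering (average linkage): returns
    the cophenetic (merge-height) matrix."""
    items = list(dist.index)
    clusters = {i: [x] for i, x in enumerate(items)}
    coph = pd.DataFrame(0.0, index=items, columns=items)
    next_id = len(items)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [dist.loc[x, y] for x in clusters[a] for y in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph.loc[x, y] = coph.loc[y, x] = d
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return coph


class TestBinaryDistance:
    def test_identical_columns_distance_zero(self):
        calls = dt.DetectionCallMatrix(
            calls=pd.DataFrame(
                [[True, True], [False, False], [True, True]],
                index=list("abc"),
                columns=["s1", "s2"],
            )
        )
        for metric in dc.METRICS:
            assert dc.binary_distance(calls, "samples", metric).loc["s1", "s2"] == 0

    def test_complementary_vectors_hamming_one(self):
        calls = dt.DetectionCallMatrix(
            calls=pd.DataFrame(
                [[True, False], [False, True], [True, False]],
                index=list("abc"),
                columns=["s1", "s2"],
            )
        )
        assert dc.binary_distance(calls, "samples", "hamming").loc["s1", "s2"] == 1.0

    def test_all_absent_pair_jaccard_zero(self):
        calls = dt.DetectionCallMatrix(
            calls=pd.DataFrame(
                [[False, False], [False, False]], index=list("ab"), columns=["s1", "s2"]
            )
        )
        assert dc.binary_distance(calls, "samples", "jaccard").loc["s1", "s2"] == 0

    @pytest.mark.parametrize("metric", dc.METRICS)
    @pytest.mark.parametrize("axis", ["samples", "mirnas"])
    def test_brute_force_pairwise_oracle(self, rng, metric, axis):
        calls = random_call_matrix(rng, 30, 8)
        d = dc.binary_distance(calls, axis, metric)
        data = calls.calls.T if axis == "samples" else calls.calls
        for a, b in itertools.combinations(data.index, 2):
            x, y = data.loc[a].to_numpy(), data.loc[b].to_numpy()
            if metric == "hamming":
                expect = (x != y).mean()
            else:
                union = (x | y).sum()
                expect = 0.0 if union == 0 else (x != y).sum() / union
            assert d.loc[a, b] == pytest.approx(expect)
            assert d.loc[b, a] == d.loc[a, b]
        assert np.allclose(np.diag(d.to_numpy()), 0)

    def test_single_item_axis_errors(self):
        calls = dt.DetectionCallMatrix(
            calls=pd.DataFrame([[True]], index=["a"], columns=["s1"])
        )
        with pytest.raises(DetectomeError, match="at least 2"):
            dc.binary_distance(calls, "samples")


class TestHCluster:
    def test_forced_topology(self):
        dist = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        dend = dc.hcluster(dist)
        # A and B merge first, C joins last -> C is alone at one end
        order = dend.leaf_order()
        assert order[0] == "C" or order[-1] == "C"
        assert dend.merges[0, 2] == pytest.approx(0.1)

    def test_non_symmetric_rejected(self):
        dist = pd.DataFrame(
            [[0, 0.1], [0.3, 0]], index=list("AB"), columns=list("AB")
        )
        with pytest.raises(DetectomeError, match="symmetric"):
            dc.hcluster(dist)

    def test_cophenetic_matches_naive_reference(self, rng):
        # real-valued random distances: ties have probability zero
        n = 10
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"i{k}" for k in range(n)]
        dist = pd.DataFrame(d, index=labels, columns=labels)
        dend = dc.hcluster(dist, "average")
        coph = pd.DataFrame(
            squareform(cophenet(dend.merges)), index=dend.labels, columns=dend.labels
        )
        ref = naive_average_linkage_cophenetic(dist)
        for a, b in itertools.combinations(labels, 2):
            assert coph.loc[a, b] == pytest.approx(ref.loc[a, b], rel=1e-9)

    def test_input_order_invariance(self, rng):
        calls = random_call_matrix(rng, 40, 9)
        dist = dc.binary_distance(calls, "samples")
        perm = list(rng.permutation(dist.index))
        shuffled = dist.loc[perm, perm]
        assert dc.hcluster(dist).to_newick() == dc.hcluster(shuffled).to_newick()

    def test_heights_non_decreasing(self, rng):
        calls = random_call_matrix(rng, 25, 12)
        for linkage in dc.LINKAGES:
            dend = dc.hcluster(dc.binary_distance(calls, "samples"), linkage)
            heights = dend.merges[:, 2]
            assert (np.diff(heights) >= -1e-12).all()


class TestDetectionMap:
    def test_identity_map_equals_input(self, rng):
        calls = random_call_matrix(rng, 15, 5)
        dmap = dc.detection_map(calls)
        pd.testing.assert_frame_equal(dmap.matrix, calls.calls)

    def test_reordering_is_pure_permutation(self, rng):
        calls = random_call_matrix(rng, 20, 8)
        dmap = dc.cluster_calls(calls)
        assert sorted(dmap.row_order) == sorted(calls.mirna_ids)
        assert sorted(dmap.col_order) == sorted(calls.sample_ids)
        pd.testing.assert_frame_equal(
            dmap.matrix.loc[calls.mirna_ids, calls.sample_ids], calls.calls
        )

    def test_leaf_mismatch_errors(self, rng):
        calls = random_call_matrix(rng, 8, 4)
        other = dc.hcluster(
            dc.binary_distance(random_call_matrix(rng, 8, 5), "samples")
        )
        with pytest.raises(DetectomeError, match="leaves"):
            dc.detection_map(calls, sample_dendrogram=other)

    def test_uniform_block_contiguous_on_synthetic_cases(
        self, default_study, default_calls, scopes
    ):
        """The all-case-shared miRNAs form one contiguous leaf block when
        clustering miRNAs of the case group, for every metric/linkage."""
        sub = default_calls.subset_samples(scopes["plasma_cases"])
        shared = dt.group_shared_set(default_calls, scopes["plasma_cases"]).members
        keep = list(sub.calls.index[sub.calls.any(axis=1)])[:400]
        keep = sorted(set(keep) | shared)
        small = dt.DetectionCallMatrix(calls=sub.calls.loc[keep].copy())
        for metric in dc.METRICS:
            order = dc.hcluster(
                dc.binary_distance(small, "mirnas", metric)
            ).leaf_order()
            pos = [i for i, m in enumerate(order) if m in shared]
            assert max(pos) - min(pos) + 1 == len(shared)
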