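"""Winner-takes-all voting, mask dilation, threshold sweep, bleed control."""

import numpy as np
import pytest
from scipy.stats import norm

from striomap.connectivity import ConnMatrix
from striomap.geometry import NETWORK_IDS, UNASSIGNED, NetworkLabelMap
from striomap.parcellation import (
    blur_sweep,
    dilate_mask,
    parcellate,
    top_k_vertices,
    vote_assign,
)


def vote_oracle(z_row, labels, k, threshold=None):
    """Exhaustive reference: full sort, explicit counting, spec tie rule."""
    order = sorted(range(len(z_row)), key=lambda i: (-z_row[i], i))[:k]
    kept = [i for i in order if labels[i] > 0 and (threshold is None or z_row[i] >= threshold)]
    counts = {}
    sums = {}
    for i in kept:
        counts[labels[i]] = counts.get(labels[i], 0) + 1
        sums[labels[i]] = sums.get(labels[i], 0.0) + z_row[i]
    if not counts:
        return UNASSIGNED, 0
    best = max(counts.values())
    tied = [n for n, c in counts.items() if c == best]
    winner = min(tied, key=lambda n: (-sums[n], n))
    return winner, len(kept)


class TestDilateMask:
    def test_level_zero_is_identity(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert np.array_equal(dilate_mask(mask, 0), mask)

    def test_single_voxel_grows_to_box(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert dilate_mask(mask, 1).sum() == 27

    def test_three_levels_compose(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12, 12)) > 0.9
        once = dilate_mask(dilate_mask(dilate_mask(mask, 1), 1), 1)
        assert np.array_equal(dilate_mask(mask, 3), once)

    def test_monotone_superset(self):
        rng = np.random.default_rng(1)
        mask = rng.random((10, 10, 10)) > 0.95
        out = dilate_mask(mask, 2)
        assert np.all(out[mask])

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            dilate_mask(np.zeros((3, 3, 3), bool), -1)


class TestTopK:
    def test_distinct_maxima_returned_in_order(self):
        z = np.array([0.1, 0.9, 0.3, 0.8, 0.2])
        assert top_k_vertices(z, 2).tolist() == [1, 3]

    def test_k_equals_count_gives_full_sort(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(30)
        assert top_k_vertices(z, 30).tolist() == np.argsort(-z, kind="stable").tolist()

    def test_matches_sort_oracle_and_default_k(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(1000)
        got = top_k_vertices(z, 400)
        oracle = sorted(range(1000), key=lambda i: (-z[i], i))[:400]
        assert got.tolist() == oracle
        assert len(got) == 400

    def test_ties_break_toward_lower_index(self):
        z = np.array([0.5, 0.7, 0.5, 0.7, 0.1])
        assert top_k_vertices(z, 3).tolist() == [1, 3, 0]

    def test_flagged_vertices_excluded(self):
        z = np.array([0.9, 0.8, 0.7])
        excluded = np.array([True, False, False])
        assert top_k_vertices(z, 2, excluded=excluded).tolist() == [1, 2]

    def test_all_flagged_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            out = top_k_vertices(np.ones(5), 3, excluded=np.ones(5, bool))
        assert out.size == 0


class TestVoteAssign:
    def test_unanimous_top_k(self):
        lang = NETWORK_IDS["LANG"]
        labels = np.full(1000, NETWORK_IDS["DN-A"], dtype=np.int16)
        labels[:400] = lang
        z = np.zeros(1000)
        z[:400] = 1.0
        res = vote_assign(z, NetworkLabelMap(labels), k=400)
        assert res.winner == lang
        assert res.counts[lang] == 400 and res.n_contributing == 400

    def test_sub_threshold_vertices_drop_from_count(self):
        """A voxel whose top 400 contains exactly 100 sub-threshold
        correlations keeps a 300-vertex vote."""
        rng = np.random.default_rng(4)
        labels = rng.integers(1, 16, size=2000).astype(np.int16)
        z = rng.uniform(-0.5, 0.02, size=2000)  # background below everything
        top = rng.choice(2000, size=400, replace=False)
        z[top[:300]] = rng.uniform(0.15, 0.9, size=300)  # above threshold
        z[top[300:]] = rng.uniform(0.05, 0.0999, size=100)  # inside top-400, below 0.10
        res = vote_assign(z, NetworkLabelMap(labels), k=400, threshold=0.10)
        assert res.n_contributing == 300
        assert res.counts.sum() == 300

    def test_all_sub_threshold_leaves_unassigned(self):
        labels = np.ones(50, dtype=np.int16)
        res = vote_assign(np.full(50, 0.05), NetworkLabelMap(labels), k=10, threshold=0.10)
        assert res.winner == UNASSIGNED and res.n_contributing == 0

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(1000):
            n = rng.integers(5, 21)
            k = int(rng.integers(1, 11))
            k = min(k, n)
            labels = rng.integers(0, 4, size=n).astype(np.int16) * 5  # 0, 5, 10, 15
            if rng.random() < 0.5:
                z = rng.standard_normal(n)
            else:  # discrete values force count and value ties
                z = rng.choice([-0.2, 0.0, 0.3, 0.3, 0.7], size=n)
            threshold = 0.1 if rng.random() < 0.3 else None
            res = vote_assign(z, NetworkLabelMap(labels), k=k, threshold=threshold)
            winner, n_contrib = vote_oracle(z, labels, k, threshold)
            assert res.winner == winner, f"trial {trial}"
            assert res.n_contributing == n_contrib

    def test_rank_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 16, size=200).astype(np.int16)
        for _ in range(20):
            z = rng.standard_normal(200)
            a = vote_assign(z, NetworkLabelMap(labels), k=50)
            b = vote_assign(np.tanh(z), NetworkLabelMap(labels), k=50)
            assert a.winner == b.winner
            assert np.array_equal(a.counts, b.counts)

    def test_empty_label_map_rejected(self):
        with pytest.raises(ValueError):
            vote_assign(np.zeros(0), NetworkLabelMap(np.zeros(0, dtype=np.int16)), k=0)


class TestParcellate:
    def _conn(self, z):
        return ConnMatrix(z=z, n_runs=1)

    def test_all_zero_with_threshold_unassigns_everything(self):
        labels = NetworkLabelMap(np.ones(30, dtype=np.int16))
        parc = parcellate(self._conn(np.zeros((10, 30))), labels, k=5, threshold=0.10)
        assert np.all(parc.winners == UNASSIGNED)
        assert parc.n_unassigned == 10

    def test_voxel_order_independence(self):
        rng = np.random.default_rng(7)
        z = rng.uniform(0.1, 0.9, size=(20, 40))
        labels = NetworkLabelMap(rng.integers(1, 16, size=40).astype(np.int16))
        perm = rng.permutation(20)
        a = parcellate(self._conn(z), labels, k=10)
        b = parcellate(self._conn(z[perm]), labels, k=10)
        assert np.array_equal(a.winners[perm], b.winners)

    def test_label_count_mismatch_rejected(self):
        labels = NetworkLabelMap(np.ones(10, dtype=np.int16))
        with pytest.raises(ValueError):
            parcellate(self._conn(np.zeros((3, 11))), labels, k=2)

    def test_provenance_recorded(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(0.1, 0.9, size=(5, 20))
        labels = NetworkLabelMap(rng.integers(1, 16, size=20).astype(np.int16))
        parc = parcellate(self._conn(z), labels, k=4, threshold=0.2)
        assert parc.params["k"] == 4 and parc.params["threshold"] == 0.2
        assert len(parc.votes) == 5
        assert all(v.counts.sum() == v.n_contributing for v in parc.votes)


class TestBlurSweep:
    def _positive_conn(self, seed=9):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0.01, 0.9, size=(30, 50))
        labels = NetworkLabelMap(rng.integers(1, 16, size=50).astype(np.int16))
        return ConnMatrix(z=z, n_runs=1), labels

    def test_threshold_zero_equals_threshold_free(self):
        conn, labels = self._positive_conn()
        free = parcellate(conn, labels, k=10)
        swept = blur_sweep(conn, labels, thresholds=[0.0], k=10)[("raw", 0.0)]
        assert np.array_equal(free.winners, swept.winners)

    def test_unassigned_sets_nest_across_thresholds(self):
        conn, labels = self._positive_conn(seed=10)
        out = blur_sweep(conn, labels, thresholds=[0.1, 0.4], k=10)
        low = out[("raw", 0.1)].winners == UNASSIGNED
        high = out[("raw", 0.4)].winners == UNASSIGNED
        assert np.all(high[low])  # unassigned at 0.1 stays unassigned at 0.4

    def test_descending_thresholds_rejected(self):
        conn, labels = self._positive_conn()
        with pytest.raises(ValueError):
            blur_sweep(conn, labels, thresholds=[0.4, 0.1], k=10)


class TestBleedDetection:
    def test_near_surface_votes_change_more_than_interior(self, recovery_study):
        """Thresholding flips near-surface assignments (bleed + rim noise)
        far more often than interior coupled voxels, pooled over seeds."""
        near_c = sum(s["bleed_change"]["near_changed"] for s in recovery_study)
        near_n = sum(s["bleed_change"]["near_total"] for s in recovery_study)
        int_c = sum(s["bleed_change"]["interior_changed"] for s in recovery_study)
        int_n = sum(s["bleed_change"]["interior_total"] for s in recovery_study)
        p_near, p_int = near_c / near_n, int_c / int_n
        assert p_near > p_int
        pooled = (near_c + int_c) / (near_n + int_n)
        se = np.sqrt(pooled * (1 - pooled) * (1 / near_n + 1 / int_n))
        z_stat = (p_near - p_int) / se
        assert norm.sf(z_stat) < 0.01
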