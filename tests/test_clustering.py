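import numpy as np
import pytest

from tomospat.clustering import (
    ClusterModel,
    cluster_summary,
    nearest_neighbors,
    proximity_fraction,
    threshold_sweep,
    topology_classify,
    trace_clusters,
)
from tomospat.particles import EmptySelectionError

from conftest import make_set


def brute_force_partition(pos, threshold, window=None):
    """Union-find over all pairwise distances: the membership oracle."""
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            ok = d <= threshold if window is None else threshold - window <= d <= threshold + window
            if ok:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


def partition_of(clusters, ids):
    idx = {pid: i for i, pid in enumerate(ids)}
    return {frozenset(idx[m] for m in c.member_ids) for c in clusters}


class TestNearestNeighbors:
    def test_pair_is_mutual(self):
        ps = make_set([[0, 0, 0], [17, 0, 0]])
        nn = nearest_neighbors(ps)
        assert list(nn["nn_dist"]) == [17.0, 17.0]

    def test_three_collinear(self):
        ps = make_set([[0, 0, 0], [17, 0, 0], [40, 0, 0]])
        nn = nearest_neighbors(ps)
        np.testing.assert_allclose(nn["nn_dist"], [17, 17, 23])

    def test_singleton_tomogram_marked_neighborless(self):
        ps = make_set([[0, 0, 0], [10, 0, 0], [5, 5, 5]], tomogram=["a", "a", "b"])
        nn = nearest_neighbors(ps)
        lone = nn[nn["tomogram_id"] == "b"]
        assert lone["nn_id"].isna().all() and lone["nn_dist"].isna().all()

    def test_matches_exhaustive_scan(self, rng):
        pos = rng.uniform(0, 300, (500, 3))
        ps = make_set(pos)
        nn = nearest_neighbors(ps)
        d = np.linalg.norm(pos[:, None] - pos[None], axis=2)
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(nn["nn_dist"].to_numpy(), d.min(axis=1))

    def test_empty_filter_raises(self, collinear_chain):
        with pytest.raises(EmptySelectionError):
            nearest_neighbors(collinear_chain, state_filter="open")


class TestTraceClusters:
    def test_chain_of_four(self, collinear_chain):
        clusters = trace_clusters(collinear_chain, threshold=20)
        assert len(clusters) == 1 and clusters[0].length == 4
        np.testing.assert_allclose(clusters[0].link_distances, [17, 17, 17])

    def test_distant_pair_not_clustered(self):
        ps = make_set([[0, 0, 0], [25, 0, 0]])
        assert trace_clusters(ps, threshold=20) == []

    def test_negative_threshold_rejected(self, collinear_chain):
        with pytest.raises(ValueError):
            trace_clusters(collinear_chain, threshold=-1)

    @pytest.mark.parametrize("window", [None, 0.5])
    def test_matches_union_find_oracle(self, rng, window):
        for _ in range(10):
            pos = rng.uniform(0, 200, (300, 3))
            ps = make_set(pos)
            clusters = trace_clusters(ps, threshold=20, window=window)
            assert partition_of(clusters, ps.df["particle_id"]) == brute_force_partition(
                pos, 20, window
            )

    def test_partition_invariant_to_input_order(self, rng):
        pos = rng.uniform(0, 150, (100, 3))
        ps = make_set(pos)
        perm = rng.permutation(100)
        ps2 = make_set(pos[perm])
        p1 = {frozenset(tuple(ps.positions[int(m[1:])]) for m in c.member_ids)
              for c in trace_clusters(ps, 20)}
        p2 = {frozenset(tuple(ps2.positions[int(m[1:])]) for m in c.member_ids)
              for c in trace_clusters(ps2, 20)}
        assert p1 == p2

    def test_partition_invariant_to_rigid_motion(self, rng):
        from tomospat.geometry import euler_to_matrix

        pos = rng.uniform(0, 150, (120, 3))
        R = euler_to_matrix((33, 70, -12))
        moved = pos @ R.T + np.array([5.0, -3.0, 11.0])
        p1 = partition_of(trace_clusters(make_set(pos), 20), make_set(pos).df["particle_id"])
        p2 = partition_of(
            trace_clusters(make_set(moved), 20), make_set(moved).df["particle_id"]
        )
        assert p1 == p2

    def test_clusters_never_span_tomograms(self):
        ps = make_set([[0, 0, 0], [17, 0, 0]], tomogram=["a", "b"])
        assert trace_clusters(ps, threshold=20) == []


class TestThresholdSweep:
    def test_pair_at_17_found_only_in_matching_bins(self):
        ps = make_set([[0, 0, 0], [17.0, 0, 0]])
        res = threshold_sweep(ps, t_min=15, t_max=20, step=0.5, window=0.5)
        t = res.table.set_index("threshold")["n_clusters"]
        # closed interval [t - 0.5, t + 0.5]: a 17.0 nm pair belongs to the
        # 16.5, 17.0 and 17.5 bins, and to neither 15 nor 20
        assert t[16.5] == t[17.0] == t[17.5] == 1
        assert t[15.0] == 0 and t[20.0] == 0 and t[16.0] == 0 and t[18.0] == 0

    def test_empty_state_yields_zero_counts(self, collinear_chain):
        res = threshold_sweep(collinear_chain, state_filter="open")
        assert (res.table["n_clusters"] == 0).all()
        assert (res.table["frac_clustered"] == 0).all()

    def test_window_must_be_positive(self, collinear_chain):
        with pytest.raises(ValueError):
            threshold_sweep(collinear_chain, window=0)

    def test_cumulative_counts_monotone_in_threshold(self, rng):
        pos = rng.uniform(0, 250, (200, 3))
        res = threshold_sweep(make_set(pos), t_min=15, t_max=40, step=1, window=None)
        counts = res.table["n_clustered_particles"].to_numpy()
        assert (np.diff(counts) >= 0).all()


class TestClusterSummary:
    def test_single_pair_flagged(self):
        clusters = trace_clusters(make_set([[0, 0, 0], [17, 0, 0]]), 20)
        s = cluster_summary(clusters, n_total=2)
        row = s.per_length.iloc[0]
        assert row["n_clusters"] == 1 and row["mean_nm"] == 17.0
        assert row["sd_nm"] == 0.0 and row["single_link"]
        assert s.clustered_fraction == 1.0

    def test_two_pairs_mean_and_sd(self):
        ps = make_set([[0, 0, 0], [16, 0, 0], [100, 0, 0], [118, 0, 0]])
        s = cluster_summary(trace_clusters(ps, 20), n_total=4)
        row = s.per_length.iloc[0]
        assert row["mean_nm"] == 17.0
        np.testing.assert_allclose(row["sd_nm"], np.sqrt(2.0), atol=1e-12)

    def test_out_of_band_links_excluded(self):
        # links at 10 and 17 nm; only the 17 nm one is in [15, 20]
        ps = make_set([[0, 0, 0], [10, 0, 0], [27, 0, 0]])
        s = cluster_summary(trace_clusters(ps, 20), d_min=15, d_max=20, n_total=3)
        assert s.per_length.iloc[0]["n_links"] == 1
        assert s.per_length.iloc[0]["mean_nm"] == 17.0

    def test_no_qualifying_links_gives_empty_table(self):
        ps = make_set([[0, 0, 0], [10, 0, 0]])
        s = cluster_summary(trace_clusters(ps, 20), d_min=15, d_max=20, n_total=2)
        assert s.per_length.empty and not s.per_length.isna().any().any()


class TestTopology:
    def test_square_is_circular(self):
        ps = make_set([[0, 0, 0], [17, 0, 0], [17, 17, 0], [0, 17, 0]])
        (c,) = trace_clusters(ps, threshold=20)
        assert topology_classify(c) == "circular"

    def test_collinear_chain_is_linear(self, collinear_chain):
        (c,) = trace_clusters(collinear_chain, threshold=20)
        assert topology_classify(c) == "linear"

    def test_pair_is_linear_by_convention(self):
        (c,) = trace_clusters(make_set([[0, 0, 0], [17, 0, 0]]), 20)
        assert topology_classify(c) == "linear"

    def test_right_angle_l_matches_direct_ratio(self):
        pts = [[0, 0, 0], [17, 0, 0], [34, 0, 0], [34, 17, 0], [34, 34, 0]]
        (c,) = trace_clusters(make_set(pts), threshold=20)
        end_to_end = np.linalg.norm(np.array(pts[-1]) - np.array(pts[0]))
        ratio = end_to_end / (4 * 17)
        expected = "linear" if ratio >= 0.8 else "other"
        assert topology_classify(c) == expected


class TestProximity:
    def test_track_within_cutoff(self):
        clusters = trace_clusters(make_set([[0, 0, 0], [17, 0, 0]]), 20)
        tracks = make_set([[17 + 19, 0, 0]], states=["actin_segment"])
        assert proximity_fraction(clusters, tracks, cutoff=20) == 1.0

    def test_track_beyond_cutoff(self):
        clusters = trace_clusters(make_set([[0, 0, 0], [17, 0, 0]]), 20)
        tracks = make_set([[17 + 21, 0, 0]], states=["actin_segment"])
        assert proximity_fraction(clusters, tracks, cutoff=20) == 0.0

    def test_no_clusters_raises(self):
        tracks = make_set([[0, 0, 0]])
        with pytest.raises(EmptySelectionError):
            proximity_fraction([], tracks)

    def test_csr_tracks_match_analytic_expectation(self, rng):
        """Poisson track field: P(no track within r of any of k members)."""
        box = np.array([400.0, 400.0, 400.0])
        n_tracks, cutoff = 400, 20.0
        lam = n_tracks / box.prod()
        hits = trials = 0
        for rep in range(60):
            tpos = rng.uniform(0, 1, (n_tracks, 3)) * box
            # one pair per replicate, placed centrally to dodge edge effects
            a = box / 2
            b = a + np.array([17.0, 0, 0])
            clusters = trace_clusters(
                make_set(np.vstack([a, b]), tomogram="t"), threshold=20
            )
            tr = make_set(tpos, states=["actin"] * n_tracks, tomogram="t")
            hits += proximity_fraction(clusters, tr, cutoff)
            trials += 1
        # union of two spheres radius 20 at centre distance 17
        r, d = cutoff, 17.0
        lens_vol = 2 * np.pi * (r - d / 2) ** 2 * (2 * r + d / 2) / 3  # sphere-sphere overlap
        union = 2 * (4 / 3) * np.pi * r**3 - lens_vol
        p_expect = 1 - np.exp(-lam * union)
        se = np.sqrt(p_expect * (1 - p_expect) / trials)
        assert abs(hits / trials - p_expect) < 3 * se + 1e-9


class TestClusterModel:
    def test_fit_reports_fraction_and_summary(self, collinear_chain):
        res = ClusterModel(collinear_chain, state="closed", threshold=20).fit()
        assert res.n_clusters == 1
        assert res.clustered_fraction == 1.0
        text = res.summary()
        assert "clustered fraction" in text and "1.000" in text
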