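import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctakit import (
    FOFParams,
    PunctaSet,
    ThomasParams,
    VolumeSpec,
    cluster_stats,
    fof_bruteforce,
    fof_grid,
    fraction_clustered_curve,
    simulate_poisson_points,
    simulate_thomas_points,
    voxel_to_physical,
)
from punctakit.errors import ParameterError

B2 = FOFParams(linking_length_um=2.0)


def partition_sets(labels):
    """Order-free view of a ClusterAssignment: frozenset of clustered index
    groups plus the set of non-clustered indices."""
    groups = {}
    noise = set()
    for idx, lab in enumerate(labels):
        if lab == 0:
            noise.add(idx)
        else:
            groups.setdefault(lab, set()).add(idx)
    return frozenset(frozenset(g) for g in groups.values()), frozenset(noise)


def kdtree_oracle(coords, b, min_size=2):
    """Independent FOF oracle: link graph from a KD-tree pair query,
    components from scipy's sparse graph machinery."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    n = len(coords)
    pairs = cKDTree(coords).query_pairs(b, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    sizes = np.bincount(comp)
    groups = {}
    noise = set()
    for idx, c in enumerate(comp):
        if sizes[c] >= min_size:
            groups.setdefault(c, set()).add(idx)
        else:
            noise.add(idx)
    return frozenset(frozenset(g) for g in groups.values()), frozenset(noise)


class TestLinkRule:
    def test_pair_inside_linking_length_links(self):
        pts = PunctaSet([[0, 0, 0], [1.9, 0, 0]])
        a = fof_bruteforce(pts, B2)
        assert a.n_clusters == 1 and np.all(a.labels == 1)

    def test_pair_beyond_linking_length_does_not_link(self):
        pts = PunctaSet([[0, 0, 0], [2.1, 0, 0]])
        a = fof_bruteforce(pts, B2)
        assert a.n_clusters == 0 and np.all(a.labels == 0)

    def test_tie_at_exact_linking_length(self):
        pts = PunctaSet([[0, 0, 0], [2.0, 0, 0]])
        assert fof_bruteforce(pts, B2).n_clusters == 1  # inclusive by default
        strict = FOFParams(2.0, strict=True)
        assert fof_bruteforce(pts, strict).n_clusters == 0

    def test_transitive_chain_is_one_cluster(self):
        # 5 points 1.5 um apart span 6 um but form a single linked network
        pts = PunctaSet([[1.5 * i, 0, 0] for i in range(5)])
        a = fof_bruteforce(pts, B2)
        assert a.n_clusters == 1 and np.all(a.labels == 1)

    def test_single_point_is_nonclustered(self):
        a = fof_bruteforce(PunctaSet([[0, 0, 0]]), B2)
        assert a.n_clusters == 0 and a.labels.tolist() == [0]

    def test_empty_input(self):
        a = fof_bruteforce(PunctaSet(np.zeros((0, 3))), B2)
        assert a.n_clusters == 0 and len(a.labels) == 0

    def test_coincident_points_form_one_cluster(self):
        pts = PunctaSet(np.zeros((6, 3)))
        for impl in (fof_bruteforce, fof_grid):
            a = impl(pts, B2)
            assert a.n_clusters == 1 and np.all(a.labels == 1)

    def test_far_apart_points_all_nonclustered(self):
        pts = PunctaSet([[10.0 * i, 0, 0] for i in range(5)])
        for impl in (fof_bruteforce, fof_grid):
            assert impl(pts, B2).n_clusters == 0


class TestGridEqualsBruteforce:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 4.0])
    def test_poisson_instances(self, seed, b):
        pts = simulate_poisson_points(0.01, VolumeSpec(50, 50, 10), seed=seed)
        params = FOFParams(b)
        assert partition_sets(fof_grid(pts, params).labels) == partition_sets(
            fof_bruteforce(pts, params).labels
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_thomas_instances_and_oracle(self, seed):
        pts = simulate_thomas_points(
            ThomasParams(0.001, 10.0, 0.5, seed=seed), VolumeSpec(50, 50, 20)
        )
        params = FOFParams(2.0)
        grid = partition_sets(fof_grid(pts, params).labels)
        brute = partition_sets(fof_bruteforce(pts, params).labels)
        oracle = kdtree_oracle(pts.coords, 2.0)
        assert grid == brute == oracle

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=0,
            max_size=60,
        ),
        st.sampled_from([0.5, 1.0, 2.0, 4.0]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_property_arbitrary_point_sets(self, points, b):
        pts = PunctaSet(np.array(points, dtype=float).reshape(-1, 3))
        params = FOFParams(b)
        assert partition_sets(fof_grid(pts, params).labels) == partition_sets(
            fof_bruteforce(pts, params).labels
        )


class TestInvariances:
    @pytest.fixture
    def field(self):
        return simulate_thomas_points(
            ThomasParams(0.0015, 8.0, 0.6, seed=3), VolumeSpec(40, 40, 10)
        )

    def test_permutation_invariance(self, field):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(field))
        base = partition_sets(fof_grid(field, B2).labels)
        shuffled = fof_grid(PunctaSet(field.coords[perm]), B2)
        # map shuffled indices back to original
        remapped, noise = partition_sets(shuffled.labels)
        remapped = frozenset(frozenset(perm[i] for i in g) for g in remapped)
        noise = frozenset(perm[i] for i in noise)
        assert (remapped, noise) == base

    def test_rigid_motion_invariance(self, field):
        base = partition_sets(fof_grid(field, B2).labels)
        shifted = PunctaSet(field.coords + np.array([13.7, -4.2, 99.0]))
        assert partition_sets(fof_grid(shifted, B2).labels) == base
        rot = field.coords[:, [1, 0, 2]] * np.array([1, -1, 1])  # 90 deg about z
        assert partition_sets(fof_grid(PunctaSet(rot), B2).labels) == base

    def test_scaling_consistency(self, field):
        base = partition_sets(fof_grid(field, B2).labels)
        scaled = PunctaSet(field.coords * 3.5)
        params = FOFParams(2.0 * 3.5)
        assert partition_sets(fof_grid(scaled, params).labels) == base

    def test_monotone_merging(self, field):
        small = fof_grid(field, FOFParams(1.0))
        large = fof_grid(field, FOFParams(2.5))
        groups_small, _ = partition_sets(small.labels)
        groups_large, _ = partition_sets(large.labels)
        for g in groups_small:
            assert sum(g <= G for G in groups_large) == 1  # contained in exactly one

    def test_anisotropy_slice_separation(self):
        """Three z-slices apart links at the 60x step but not at the 20x step."""
        for dz, should_link in ((0.45, True), (1.4, False)):
            vs = (0.2, 0.2, dz)
            p0 = voxel_to_physical((0, 10, 10), vs)
            p1 = voxel_to_physical((3, 10, 10), vs)
            a = fof_bruteforce(PunctaSet([p0, p1]), B2)
            assert (a.n_clusters == 1) is should_link


class TestClusterStats:
    def test_all_nonclustered(self):
        pts = PunctaSet([[0, 0, 0], [50, 0, 0], [0, 50, 0]])
        stats = cluster_stats(fof_grid(pts, B2))
        assert stats.fraction_clustered == 0.0 and stats.size_histogram == {}

    def test_mixed_partition_arithmetic(self):
        # one cluster of 4, one of 2, four singletons -> fraction 0.6
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]  # cluster of 4
            + [[30, 0, 0], [31, 0, 0]]  # cluster of 2
            + [[60, 0, 0], [60, 30, 0], [90, 0, 0], [90, 30, 0]],  # singletons
            dtype=float,
        )
        stats = cluster_stats(fof_grid(PunctaSet(pts), B2))
        assert stats.fraction_clustered == pytest.approx(0.6)
        assert stats.size_histogram == {4: 1, 2: 1}
        assert sum(k * v for k, v in stats.size_histogram.items()) == stats.n_clustered

    def test_empty_set_fraction_zero_by_convention(self):
        stats = cluster_stats(fof_grid(PunctaSet(np.zeros((0, 3))), B2))
        assert stats.fraction_clustered == 0.0 and stats.n_total == 0

    def test_deterministic_label_order(self):
        # labels assigned by decreasing size, ties by smallest member index
        pts = PunctaSet(
            [[50, 0, 0], [51, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]]
        )
        a = fof_grid(pts, B2)
        assert a.labels.tolist() == [2, 2, 1, 1, 1]


class TestFractionCurve:
    def test_monotone_in_linking_length(self):
        for seed in range(5):
            pts = simulate_thomas_points(
                ThomasParams(0.001, 8.0, 0.7, seed=seed), VolumeSpec(50, 50, 10)
            )
            curve = fraction_clustered_curve(pts, [1.0, 2.0, 4.0])
            fracs = [f for _, f in curve]
            assert fracs == sorted(fracs)

    def test_extreme_lengths(self):
        pts = simulate_poisson_points(0.005, VolumeSpec(30, 30, 10), seed=1)
        curve = dict(fraction_clustered_curve(pts, [0.001, 100.0]))
        assert curve[0.001] == 0.0
        assert curve[100.0] == 1.0

    def test_unsorted_lengths_rejected(self):
        with pytest.raises(ParameterError):
            fraction_clustered_curve(PunctaSet([[0, 0, 0]]), [2.0, 1.0])

    def test_min_cluster_size_validation(self):
        with pytest.raises(ParameterError):
            FOFParams(2.0, min_cluster_size=1)
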