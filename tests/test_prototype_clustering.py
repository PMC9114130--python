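import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from colonymorph.io_formats import CondensedDistances
from colonymorph.prototype_clustering import (
    CH_DEGENERATE,
    ch_index,
    cut_at,
    minimax_linkage,
    minimax_radius,
    select_cut,
)


def bruteforce_minimax_linkage(D):
    """Independent oracle: recompute every pairwise cluster linkage at each
    step from the definition, with the same tie rules (smallest node-index
    pair; prototype ties to the smallest leaf)."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                union = sorted(clusters[a] + clusters[b])
                radius = min(max(D[c][x] for x in union) for c in union)
                if best is None or radius < best[0] or (radius == best[0] and (a, b) < best[1]):
                    best = (radius, (a, b), union)
        radius, (a, b), union = best
        proto = min(
            (max(D[c][x] for x in union), c) for c in union
        )[1]
        merges.append((a, b, radius, len(union), proto))
        del clusters[a], clusters[b]
        clusters[n + step] = union
    return merges


def random_instance(seed, n=None):
    r = np.random.default_rng(seed)
    n = n or int(r.integers(2, 13))
    pts = r.normal(size=(n, 3))
    return squareform(pdist(pts))


class TestMinimaxRadius:
    def test_singleton(self):
        D = np.zeros((3, 3))
        assert minimax_radius([1], D) == (0.0, 1)

    def test_three_points_on_a_line(self):
        # points at 0, 1, 3: candidate max-distances are 3, 2, 3
        D = squareform(pdist(np.array([[0.0], [1.0], [3.0]])))
        radius, proto = minimax_radius([0, 1, 2], D)
        assert radius == 2.0 and proto == 1

    def test_equilateral_tie_goes_to_lowest_index(self):
        D = np.full((3, 3), 0.7)
        np.fill_diagonal(D, 0)
        radius, proto = minimax_radius([0, 1, 2], D)
        assert radius == 0.7 and proto == 0


class TestMinimaxLinkage:
    def test_two_leaves_height_is_distance(self):
        cd = CondensedDistances(ids=["a", "b"], values=np.array([0.9]))
        dendro = minimax_linkage(cd)
        m = dendro.merges[0]
        assert m.height == 0.9 and m.size == 2 and m.prototype == 0

    def test_three_points_on_a_line_merge_order(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [3.0]])))
        dendro = minimax_linkage(D)
        first, second = dendro.merges
        assert (first.left, first.right) == (0, 1) and first.height == 1.0
        assert second.height == 2.0 and second.prototype == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence(self, seed):
        D = random_instance(seed)
        dendro = minimax_linkage(D)
        expected = bruteforce_minimax_linkage(D)
        for m, (a, b, h, size, proto) in zip(dendro.merges, expected):
            assert (m.left, m.right) == (a, b)
            assert m.height == pytest.approx(h)
            assert m.size == size and m.prototype == proto

    @pytest.mark.parametrize("seed", range(10))
    def test_heights_monotone(self, seed):
        D = random_instance(seed + 1000)
        heights = [m.height for m in minimax_linkage(D).merges]
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_prototype_covers_subtree_at_height(self, seed):
        D = random_instance(seed + 2000)
        dendro = minimax_linkage(D)
        members = dendro.node_members()
        for i, m in enumerate(dendro.merges):
            leaves = members[dendro.n_leaves + i]
            assert max(D[m.prototype][x] for x in leaves) == pytest.approx(m.height)

    def test_permutation_equivariance(self):
        D = random_instance(77, n=9)
        perm = np.random.default_rng(0).permutation(9)
        Dp = D[np.ix_(perm, perm)]
        h1 = sorted(m.height for m in minimax_linkage(D).merges)
        h2 = sorted(m.height for m in minimax_linkage(Dp).merges)
        np.testing.assert_allclose(h1, h2)
        # prototypes map through the permutation at every cut size
        for k in (2, 3, 4):
            cut = cut_at(minimax_linkage(D), k=k)
            cutp = cut_at(minimax_linkage(Dp), k=k)
            protos = {frozenset(np.flatnonzero(cut.labels == c)) for c in range(k)}
            protos_p = {
                frozenset(perm[np.flatnonzero(cutp.labels == c)]) for c in range(k)
            }
            assert protos == protos_p

    def test_nonfinite_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            minimax_linkage(D)


@pytest.fixture(scope="module")
def dendro():
    return minimax_linkage(random_instance(5, n=10))


class TestCuts:

    def test_above_root_single_cluster(self, dendro):
        cut = cut_at(dendro, height=dendro.merges[-1].height + 1)
        assert cut.k == 1
        assert cut.prototypes[0] == dendro.root_prototype

    def test_just_below_root_two_clusters(self, dendro):
        h = dendro.merges[-1].height
        prev = dendro.merges[-2].height
        cut = cut_at(dendro, height=(h + prev) / 2)
        assert cut.k == 2

    def test_negative_height_all_singletons(self, dendro):
        cut = cut_at(dendro, height=-1.0)
        assert cut.k == 10
        assert all(cut.prototypes[c] == c for c in range(10))

    @pytest.mark.parametrize("k", [2, 3, 5, 9])
    def test_k_cut_equals_height_cut_between_merges(self, dendro, k):
        n = dendro.n_leaves
        lo = dendro.merges[n - k - 1].height
        hi = dendro.merges[n - k].height if k > 1 else lo + 1
        if hi <= lo:  # tied heights: no strict gap to cut in
            pytest.skip("tied merge heights")
        by_k = cut_at(dendro, k=k)
        by_h = cut_at(dendro, height=(lo + hi) / 2)
        np.testing.assert_array_equal(by_k.labels, by_h.labels)
        assert by_k.prototypes == by_h.prototypes


def blobs(k, per, spread=0.05, seed=0):
    r = np.random.default_rng(seed)
    centers = 10 * r.normal(size=(k, 3))
    X = np.concatenate([c + spread * r.normal(size=(per, 3)) for c in centers])
    labels = np.repeat(np.arange(k), per)
    return X, labels


class TestCHIndex:
    def test_true_k_beats_finer_cuts(self):
        X, labels = blobs(2, 20)
        D = squareform(pdist(X))
        dendro = minimax_linkage(D)
        scores = {k: ch_index(cut_at(dendro, k=k).labels, X) for k in (2, 3, 4)}
        assert scores[2] > scores[3] and scores[2] > scores[4]

    def test_degenerate_zero_within_scatter(self):
        X = np.repeat([[0.0, 0, 0], [1.0, 0, 0]], 3, axis=0)
        labels = np.repeat([0, 1], 3)
        assert ch_index(labels, X) == CH_DEGENERATE

    def test_true_labels_beat_random_labels(self):
        X, labels = blobs(3, 15, seed=3)
        shuffled = np.random.default_rng(0).permutation(labels)
        assert ch_index(labels, X) > ch_index(shuffled, X)

    def test_matches_sklearn(self, rng):
        X = rng.normal(size=(40, 5))
        labels = rng.integers(0, 4, size=40)
        if len(set(labels.tolist())) < 2:
            labels[0] = (labels[0] + 1) % 4
        assert ch_index(labels, X) == pytest.approx(calinski_harabasz_score(X, labels))

    def test_k_out_of_range_raises(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="undefined"):
            ch_index(np.zeros(4, dtype=int), X)


class TestSelectCut:
    def test_two_planted_blobs(self):
        X, labels = blobs(2, 12, seed=7)
        dendro = minimax_linkage(squareform(pdist(X)))
        cut = select_cut(dendro, X)
        assert cut.k == 2
        assert len(set(zip(cut.labels, labels))) == 2  # exact recovery

    def test_four_planted_blobs_prototypes_distinct(self):
        X, labels = blobs(4, 12, seed=11)
        dendro = minimax_linkage(squareform(pdist(X)))
        cut = select_cut(dendro, X)
        assert cut.k == 4
        proto_classes = {labels[leaf] for leaf in cut.prototypes.values()}
        assert len(proto_classes) == 4

    def test_forced_k_range(self):
        X, _ = blobs(3, 8, seed=2)
        dendro = minimax_linkage(squareform(pdist(X)))
        cut = select_cut(dendro, X, k_range=(2, 2))
        assert cut.k == 2
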