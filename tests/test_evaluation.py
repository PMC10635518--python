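import numpy as np
import pytest
from scipy import stats as sps

from pitmatch.core import (
    OUTLIER,
    UNLABELED,
    GraphPopulation,
    SulcalGraph,
    bulk_from_ground_truth,
    bulk_from_pairs,
    pad_population,
)
from pitmatch.evaluation import (
    MatchScore,
    centroids_and_silhouette,
    graph_consistency,
    group_ttest,
    match_counts,
    node_consistency,
    node_consistency_all,
    percent_unmatched,
    propagate_labels,
)
from conftest import small_population, noiseless_population


def unit_graph(coords, **kw):
    coords = np.asarray(coords, float)
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    return SulcalGraph(coords, **kw)


def toy_swap_bulk():
    """N=3 graphs of 2 nodes: X_12 = X_23 = I but X_13 swaps."""
    I, S = np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]])
    return bulk_from_pairs({(0, 1): I, (0, 2): S, (1, 2): I}, 3, 2)


class TestMatchCounts:
    def test_perfect_prediction(self):
        pop, gt, _ = small_population()
        padded = pad_population(pop)
        bulk = bulk_from_ground_truth(gt, padded)
        s = match_counts(bulk, gt, padded)
        assert s.precision == s.recall == s.f1 == 1.0

    def test_formulas_from_counts(self):
        s = MatchScore(true_positives=2, false_positives=1, false_negatives=1)
        assert s.precision == pytest.approx(2 / 3)
        assert s.recall == pytest.approx(2 / 3)
        assert s.f1 == pytest.approx(2 / 3)
        assert MatchScore(0, 0, 0).f1 == 0.0   # 0/0 convention

    def test_outlier_match_counts_as_false_positive(self):
        # two graphs with identities [A, B, OUT]; prediction matches A-A
        # (correct) and B-OUT (false positive); B-B is missed
        g = unit_graph([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        pop = GraphPopulation([g, unit_graph(g.coords.copy())])
        gt = [np.array([0, 1, OUTLIER]), np.array([0, 1, OUTLIER])]
        X = np.zeros((3, 3))
        X[0, 0] = 1.0
        X[1, 2] = 1.0
        bulk = bulk_from_pairs({(0, 1): X}, 2, 3)
        s = match_counts(bulk, gt, pop)
        assert (s.true_positives, s.false_positives, s.false_negatives) == (1, 1, 1)
        assert s.f1 == pytest.approx(0.5)


class TestConsistency:
    def test_consistent_bulk_gives_one_everywhere(self, rng):
        n, N = 4, 4
        P = [np.eye(n)[rng.permutation(n)] for _ in range(N)]
        bulk = bulk_from_pairs(
            {(i, j): P[i] @ P[j].T for i in range(N) for j in range(i + 1, N)}, N, n
        )
        for k in range(N):
            assert np.allclose(node_consistency(bulk, k), 1.0)
            assert graph_consistency(bulk, k) == pytest.approx(1.0)

    def test_swap_toy_node_value(self):
        bulk = toy_swap_bulk()
        # single inconsistent pair contributes a row norm sqrt(2)/2 over 3 pairs
        expected = 1.0 - (np.sqrt(2) / 2) / 3
        c = node_consistency(bulk, 0)
        assert c[0] == pytest.approx(expected)
        assert c[0] == pytest.approx(0.7643, abs=5e-5)

    def test_swap_toy_graph_value(self):
        bulk = toy_swap_bulk()
        # ||I - swap||_F = 2 over 2 n_q = 4, averaged over 3 pairs
        assert graph_consistency(bulk, 0) == pytest.approx(1 - 0.5 / 3)
        assert graph_consistency(bulk, 0) == pytest.approx(0.8333, abs=5e-5)

    def test_invariant_under_consistent_relabeling(self, rng):
        n, N = 5, 4
        pairs = {}
        for i in range(N):
            for j in range(i + 1, N):
                X = np.zeros((n, n))
                perm = rng.permutation(n)
                keep = rng.random(n) < 0.8
                X[np.arange(n)[keep], perm[keep]] = 1.0
                pairs[(i, j)] = X
        bulk = bulk_from_pairs(pairs, N, n)
        Q = [np.eye(n)[rng.permutation(n)] for _ in range(N)]
        conj = {
            (i, j): Q[i] @ pairs[(i, j)] @ Q[j].T
            for i in range(N) for j in range(i + 1, N)
        }
        bulk2 = bulk_from_pairs(conj, N, n)
        for k in range(N):
            c1 = node_consistency(bulk, k)
            c2 = node_consistency(bulk2, k)
            assert np.allclose(Q[k] @ c1, c2)

    def test_graph_vs_node_consistency_bound(self, rng):
        n, N = 4, 4
        pairs = {}
        for i in range(N):
            for j in range(i + 1, N):
                pairs[(i, j)] = np.eye(n)[rng.permutation(n)]
        bulk = bulk_from_pairs(pairs, N, n)
        mean_graph = np.mean([graph_consistency(bulk, q) for q in range(N)])
        min_node = min(node_consistency(bulk, k).min() for k in range(N))
        assert mean_graph >= min_node - 1e-12


class TestPropagateLabels:
    def test_consistent_population_fully_labeled(self):
        pop, gt, _ = noiseless_population()
        padded = pad_population(pop)
        bulk = bulk_from_ground_truth(gt, padded)
        labeling = propagate_labels(bulk, padded)
        n_ref = padded[0].n_real
        for lab, g in zip(labeling, padded):
            real = lab[~g.dummy]
            assert sorted(real) == list(range(n_ref))
        assert percent_unmatched(labeling, padded) == 0.0

    def test_partial_bulk_leaves_unlabeled(self):
        pop, gt, _ = noiseless_population()
        padded = pad_population(pop)
        bulk = bulk_from_ground_truth(gt, padded)
        ref = int(np.argmax([g.n_real for g in padded]))
        other = (ref + 1) % len(padded)
        i, j = min(ref, other), max(ref, other)
        X = bulk.block(i, j).copy()
        X[0, :] = 0.0   # unmatch node 0 of graph i against the reference pair
        bulk.set_block(i, j, X)
        bulk.set_block(j, i, X.T)
        labeling = propagate_labels(bulk, padded)
        assert (labeling[other] == UNLABELED).sum() == 1
        assert percent_unmatched(labeling, padded) > 0.0

    def test_label_permutation_only_renames_clusters(self, rng):
        pop, gt, _ = noiseless_population()
        padded = pad_population(pop)
        bulk = bulk_from_ground_truth(gt, padded)
        labeling = propagate_labels(bulk, padded)
        rep = centroids_and_silhouette(labeling, padded)
        # renaming reference labels with a fixed permutation changes ids only
        perm = rng.permutation(padded[0].n_real)
        renamed = [np.where(l == UNLABELED, UNLABELED, perm[l]) for l in labeling]
        rep2 = centroids_and_silhouette(renamed, padded)
        assert rep2.n_clusters == rep.n_clusters
        assert rep2.mean_silhouette == pytest.approx(rep.mean_silhouette)
        s1 = rep.clusters.sort_values("label").silhouette.to_numpy()
        s2 = rep2.clusters.set_index("label").loc[perm].silhouette.to_numpy()
        assert np.allclose(s1, s2)


def brute_force_silhouette(X, y):
    n = len(y)
    out = np.zeros(n)
    for i in range(n):
        same = (y == y[i]) & (np.arange(n) != i)
        if not same.any():
            out[i] = 0.0
            continue
        a = np.mean(np.linalg.norm(X[same] - X[i], axis=1))
        b = np.inf
        for lbl in np.unique(y):
            if lbl == y[i]:
                continue
            other = y == lbl
            b = min(b, np.mean(np.linalg.norm(X[other] - X[i], axis=1)))
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


class TestSilhouette:
    def test_tight_antipodal_clusters(self, rng):
        base1, base2 = np.array([0, 0, 1.0]), np.array([0, 0, -1.0])
        graphs, labeling = [], []
        for _ in range(4):
            c1 = base1 + 1e-3 * rng.standard_normal(3)
            c2 = base2 + 1e-3 * rng.standard_normal(3)
            graphs.append(unit_graph([c1, c2]))
            labeling.append(np.array([0, 1]))
        rep = centroids_and_silhouette(labeling, GraphPopulation(graphs))
        assert rep.n_clusters == 2
        assert (rep.clusters.silhouette > 0.99).all()
        assert abs(rep.clusters.iloc[0][["centroid_x", "centroid_y", "centroid_z"]]
                   @ base1) > 0.999

    def test_equidistant_node_scores_zero(self):
        g1 = unit_graph([[1, 0, 0], [0, 1, 0]])
        g2 = unit_graph([[0, 0, 1], [0, 1, 0]])
        # node 0 of g1: own-cluster mate at sqrt(2), other cluster at sqrt(2)
        labeling = [np.array([0, 1]), np.array([0, 1])]
        pop = GraphPopulation([g1, g2])
        rep = centroids_and_silhouette(labeling, pop)
        # recompute per-node values with the oracle to locate node 0
        X = np.vstack([g1.coords[[0]], g2.coords[[0]]])
        assert brute_force_silhouette(
            np.vstack([g1.coords, g2.coords]),
            np.array([0, 1, 0, 1]),
        )[0] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.standard_normal((30, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        y = rng.integers(0, 4, size=30)
        graphs = [unit_graph(pts[:15]), unit_graph(pts[15:])]
        labeling = [y[:15], y[15:]]
        rep = centroids_and_silhouette(labeling, GraphPopulation(graphs))
        oracle = brute_force_silhouette(pts, y)
        for _, row in rep.clusters.iterrows():
            assert row.silhouette == pytest.approx(
                oracle[y == row.label].mean(), abs=1e-9
            )
        assert rep.mean_silhouette == pytest.approx(oracle.mean(), abs=1e-9)

    def test_single_cluster_rejected(self):
        g = unit_graph([[1, 0, 0], [0, 1, 0]])
        with pytest.raises(ValueError):
            centroids_and_silhouette(
                [np.zeros(2, int), np.zeros(2, int)],
                GraphPopulation([g, unit_graph(g.coords.copy())]),
            )


def population_with_depths(depths):
    """One single-node graph per subject carrying a depth attribute."""
    graphs = []
    for d in depths:
        g = unit_graph([[0, 0, 1.0]])
        g.node_attrs["depth"] = np.array([float(d)])
        graphs.append(g)
    return GraphPopulation(graphs)


class TestGroupTTest:
    def test_identical_groups_give_zero_t(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        pop = population_with_depths(vals + vals)
        labeling = [np.array([0])] * 8
        groups = np.array([0] * 4 + [1] * 4)
        res = group_ttest(labeling, pop, groups)
        assert res.t.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.n1.iloc[0] == 4 and res.n2.iloc[0] == 4

    def test_sign_convention_group0_deeper_is_positive(self):
        pop = population_with_depths([5.0, 5.1, 4.9, 5.0, 1.0, 1.1, 0.9, 1.0])
        labeling = [np.array([0])] * 8
        res = group_ttest(labeling, pop, np.array([0] * 4 + [1] * 4))
        assert res.t.iloc[0] > 0

    def test_matches_scipy_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 9)
        pop = population_with_depths(np.concatenate([a, b]))
        labeling = [np.array([0])] * 16
        res = group_ttest(labeling, pop, np.array([0] * 7 + [1] * 9))
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.t.iloc[0] == pytest.approx(t)
        assert res.p.iloc[0] == pytest.approx(p)

    def test_small_group_skipped(self):
        pop = population_with_depths([1.0, 2.0, 3.0])
        labeling = [np.array([0])] * 3
        res = group_ttest(labeling, pop, np.array([0, 0, 1]))
        assert np.isnan(res.t.iloc[0])
        assert "skipped" in res.note.iloc[0]

    def test_rejection_rate_matches_power_oracle(self, rng):
        # pooled two-sample t-test with n1 = n2 = 15 and shift delta:
        # power from the noncentral t distribution
        n1 = n2 = 15
        delta, alpha = 1.0, 0.05
        df = n1 + n2 - 2
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        nc = delta / np.sqrt(1 / n1 + 1 / n2)
        power = 1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        groups = np.array([0] * n1 + [1] * n2)
        labeling = [np.array([0])] * (n1 + n2)
        reps, hits = 400, 0
        for _ in range(reps):
            vals = np.concatenate([rng.normal(delta, 1, n1), rng.normal(0, 1, n2)])
            pop = population_with_depths(vals)
            res = group_ttest(labeling, pop, groups)
            hits += res.p.iloc[0] < alpha
        se = np.sqrt(power * (1 - power) / reps)
        assert hits / reps == pytest.approx(power, abs=4 * se)
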