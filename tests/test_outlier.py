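import numpy as np
import pandas as pd
import pytest

from fragilome.outlier import (
    FeatureMatrix,
    choose_k,
    compute_linkage,
    cross_tabulate,
    embed_centroids,
    flag_outliers,
    hierarchical_cluster,
    standardize,
    variance_explained,
)


def make_features(values, prefix="g"):
    values = np.asarray(values, float)
    return FeatureMatrix(
        ids=tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        columns=tuple(f"f{j}" for j in range(values.shape[1])),
        values=values,
    )


@pytest.fixture(scope="module")
def blobs():
    """Three Gaussian blobs separated by ~10 internal sds."""
    r = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts = np.vstack([r.normal(c, 1.0, size=(20, 2)) for c in centers])
    labels = np.repeat([1, 2, 3], 20)
    return make_features(pts), labels


def naive_lance_williams(points, method):
    """Independent O(n^3) agglomerative oracle, pure-python bookkeeping."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(points))
    if method == "ward2":
        D = D**2  # operate on squared distances, take sqrt of heights
    clusters = {i: [i] for i in range(len(points))}
    dist = {
        (i, j): D[i, j]
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(np.sqrt(h) if method == "ward2" else h)
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) + clusters.pop(j)
        new_dist = {}
        for m in clusters:
            nm = len(clusters[m])
            dim = dist[(min(i, m), max(i, m))]
            djm = dist[(min(j, m), max(j, m))]
            if method == "complete":
                d = max(dim, djm)
            else:  # ward recurrence (raw for ward.D, squared for ward2)
                d = ((ni + nm) * dim + (nj + nm) * djm - nm * h) / (ni + nj + nm)
            new_dist[(min(m, next_id), max(m, next_id))] = d
        dist = {
            k: v for k, v in dist.items() if i not in k and j not in k
        }
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    return np.array(heights)


class TestStandardize:
    def test_zero_mean_unit_sd(self, blobs):
        fm, _ = blobs
        z = standardize(fm)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-9)
        assert z.standardized

    def test_constant_column_zeroed_with_warning(self):
        fm = make_features([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = standardize(fm)
        assert (z.values[:, 0] == 0.0).all()

    def test_idempotent(self, blobs):
        fm, _ = blobs
        once = standardize(fm)
        twice = standardize(once)
        assert np.allclose(once.values, twice.values)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(make_features([[1.0, 2.0]]))


class TestHierarchicalCluster:
    def test_singletons_at_k_equals_n(self, blobs):
        fm, _ = blobs
        model = hierarchical_cluster(fm, "complete", k=len(fm.ids))
        assert model.k == len(fm.ids)
        assert (model.sizes == 1).all()

    @pytest.mark.parametrize("linkage_method", ["complete", "ward", "ward2"])
    def test_planted_blob_recovery(self, blobs, linkage_method):
        fm, truth = blobs
        model = hierarchical_cluster(fm, linkage_method, k=3)
        tab = pd.crosstab(truth, model.labels)
        assert (tab.to_numpy() > 0).sum() == 3  # one-to-one match

    @pytest.mark.parametrize("linkage_method", ["complete", "ward", "ward2"])
    def test_merge_heights_match_naive_oracle(self, linkage_method, rng):
        pts = rng.normal(size=(20, 3))
        Z = compute_linkage(make_features(pts), linkage_method)
        oracle = naive_lance_williams(pts, linkage_method)
        assert np.allclose(np.sort(Z[:, 2]), np.sort(oracle), atol=1e-8)

    def test_permutation_invariant_partition(self, blobs, rng):
        fm, _ = blobs
        model = hierarchical_cluster(fm, "ward", k=3)
        perm = rng.permutation(len(fm.ids))
        shuffled = FeatureMatrix(
            ids=tuple(fm.ids[i] for i in perm),
            columns=fm.columns,
            values=fm.values[perm],
        )
        model2 = hierarchical_cluster(shuffled, "ward", k=3)
        a = model.labels_series()
        b = model2.labels_series().reindex(a.index)
        assert pd.crosstab(a, b).gt(0).sum().sum() == 3

    def test_k_bounds(self, blobs):
        fm, _ = blobs
        with pytest.raises(ValueError):
            hierarchical_cluster(fm, "ward", k=len(fm.ids) + 1)

    def test_nan_rejected(self):
        fm = make_features([[1.0, np.nan], [0.0, 1.0], [2.0, 0.5]])
        with pytest.raises(ValueError, match="NaN"):
            compute_linkage(fm, "complete")


class TestChooseK:
    def test_recovers_three_blobs(self, blobs):
        fm, _ = blobs
        Z = compute_linkage(fm, "ward")
        assert choose_k(fm, Z, k_max=10) == 3

    def test_range_contract_and_determinism(self, rng):
        fm = make_features(rng.normal(size=(30, 4)))
        Z = compute_linkage(fm, "complete")
        k1 = choose_k(fm, Z, k_max=8)
        k2 = choose_k(fm, Z, k_max=8)
        assert 2 <= k1 <= 8
        assert k1 == k2

    def test_k_max_floor(self, blobs):
        fm, _ = blobs
        Z = compute_linkage(fm, "ward")
        with pytest.raises(ValueError):
            choose_k(fm, Z, k_max=1)


class TestEmbedCentroids:
    def test_planar_centroids_recovered_exactly(self, rng):
        from scipy.spatial.distance import pdist

        pts = rng.normal(size=(6, 2))
        fm = make_features(pts)
        model = hierarchical_cluster(fm, "complete", k=6)  # centroids = points
        emb = embed_centroids(model)
        assert np.allclose(pdist(emb.coords), pdist(model.centroids), atol=1e-8)
        assert emb.stress < 1e-10

    def test_collinear_centroids_give_one_dimension(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        model = hierarchical_cluster(make_features(pts), "complete", k=4)
        emb = embed_centroids(model)
        spans = np.ptp(emb.coords, axis=0)
        assert min(spans) < 1e-6 < max(spans)

    def test_matches_eigendecomposition_oracle(self, rng):
        from scipy.spatial.distance import pdist, squareform

        pts = rng.normal(size=(8, 5))
        model = hierarchical_cluster(make_features(pts), "complete", k=8)
        emb = embed_centroids(model)
        # independent strain-minimizing oracle on the same centroid order
        D2 = squareform(pdist(model.centroids)) ** 2
        n = 8
        J = np.eye(n) - 1 / n
        B = -0.5 * J @ D2 @ J
        w, v = np.linalg.eigh(B)
        top = np.argsort(w)[::-1][:2]
        oracle = v[:, top] * np.sqrt(w[top])
        assert np.allclose(pdist(emb.coords), pdist(oracle), atol=1e-8)

    def test_needs_three_centroids(self, blobs):
        fm, _ = blobs
        model = hierarchical_cluster(fm, "ward", k=2)
        with pytest.raises(ValueError):
            embed_centroids(model)


class TestCrossTabulate:
    def test_identical_labelings_diagonal(self):
        lab = pd.Series([1, 1, 2, 2, 3], index=list("abcde"))
        tab = cross_tabulate(lab, lab)
        inner = tab.drop("Sum").drop(columns="Sum").to_numpy()
        assert (inner == np.diag([2, 2, 1])).all()

    def test_marginals_conserved(self, blobs):
        fm, truth = blobs
        m1 = hierarchical_cluster(fm, "ward", k=3)
        m2 = hierarchical_cluster(fm, "complete", k=4)
        tab = cross_tabulate(m1, m2)
        n = len(fm.ids)
        assert tab.loc["Sum", "Sum"] == n
        assert (tab.drop("Sum")["Sum"].to_numpy() == m1.sizes).all()

    def test_id_mismatch_rejected(self):
        a = pd.Series([1, 2], index=["x", "y"])
        b = pd.Series([1, 2], index=["x", "z"])
        with pytest.raises(ValueError, match="different genome sets"):
            cross_tabulate(a, b)


class TestVarianceExplained:
    def test_labels_equal_value_groups_give_100(self):
        fm = make_features([[1.0], [1.0], [5.0], [5.0]])
        lab = pd.Series([1, 1, 2, 2], index=fm.ids)
        assert variance_explained(fm, lab).iloc[0] == pytest.approx(100.0)

    def test_singletons_give_100_everywhere(self, rng):
        fm = make_features(rng.normal(size=(6, 3)))
        lab = pd.Series(range(1, 7), index=fm.ids)
        assert np.allclose(variance_explained(fm, lab), 100.0)

    def test_single_cluster_zero(self, rng):
        fm = make_features(rng.normal(size=(5, 2)))
        lab = pd.Series([1] * 5, index=fm.ids)
        assert (variance_explained(fm, lab) == 0.0).all()

    def test_matches_anova_oracle(self, rng):
        import statsmodels.formula.api as smf

        fm = make_features(rng.normal(size=(40, 3)))
        lab = pd.Series(rng.integers(1, 5, size=40), index=fm.ids)
        got = variance_explained(fm, lab)
        for j, col in enumerate(fm.columns):
            df = pd.DataFrame({"y": fm.values[:, j], "g": lab.to_numpy()})
            r2 = smf.ols("y ~ C(g)", data=df).fit().rsquared
            assert got[col] == pytest.approx(100.0 * r2, abs=1e-10)


class TestFlagOutliers:
    def test_homogeneous_blob_empty(self, rng):
        fm = make_features(rng.normal(size=(50, 3)))
        model = hierarchical_cluster(fm, "ward", k=3)
        rep = flag_outliers(model, max_size_fraction=0.05)
        assert rep.flagged_ids == ()

    def test_planted_outliers_flagged(self, rng):
        bulk = rng.normal(0.0, 1.0, size=(96, 2))
        outliers = rng.normal(30.0, 1.0, size=(4, 2))
        fm = make_features(np.vstack([bulk, outliers]))
        model = hierarchical_cluster(fm, "ward", k=3)
        rep = flag_outliers(model, max_size_fraction=0.05, min_centroid_separation=1.0)
        assert set(rep.flagged_ids) == {f"g{i}" for i in range(96, 100)}
        assert rep.rationale  # each flagged cluster explains itself

    def test_monotone_in_size_fraction(self, rng):
        bulk = rng.normal(0.0, 1.0, size=(90, 2))
        outliers = rng.normal(25.0, 1.0, size=(10, 2))
        fm = make_features(np.vstack([bulk, outliers]))
        model = hierarchical_cluster(fm, "ward", k=4)
        prev: set = set()
        for frac in (0.01, 0.05, 0.2):
            rep = flag_outliers(model, max_size_fraction=frac, min_centroid_separation=1.0)
            assert prev <= set(rep.flagged_ids)
            prev = set(rep.flagged_ids)
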