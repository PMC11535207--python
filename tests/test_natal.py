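"""Buffer composition, the scaled PCA, projection and clustering."""

import itertools

import numpy as np
import pytest

from nhpikit.landscape import LAND_COVER_CLASSES, LandscapeRaster
from nhpikit.natal import (
    ExtractionError,
    HabitatVector,
    cluster_natal_habitats,
    compute_score_grid,
    extract_buffer_composition,
    fit_natal_pca,
    project,
)


def _uniform_landscape(cls="forest", n=60, elev=600.0):
    code = LAND_COVER_CLASSES.index(cls)
    return LandscapeRaster(
        x0=0, y0=0, cell_size=100.0,
        elevation=np.full((n, n), elev),
        land_cover=np.full((n, n), code, dtype=int),
    )


def _random_vectors(rng, n=20):
    props = rng.dirichlet(np.ones(6), size=n)
    return [
        HabitatVector(
            elevation=float(rng.uniform(400, 1200)),
            proportions=dict(zip(LAND_COVER_CLASSES, p)),
        )
        for p in props
    ]


class TestExtractBufferComposition:
    def test_uniform_raster_gives_pure_class(self):
        land = _uniform_landscape("forest")
        hv = extract_buffer_composition(land, (3000.0, 3000.0), 2000.0)
        assert hv.proportions["forest"] == 1.0
        assert sum(hv.proportions.values()) == 1.0
        assert hv.elevation == 600.0

    def test_half_plane_split_is_symmetric(self):
        land = _uniform_landscape("arable")
        land.land_cover[:, 30:] = LAND_COVER_CLASSES.index("forest")
        hv = extract_buffer_composition(land, (3000.0, 3000.0), 2000.0)
        # boundary runs through the point: proportions near 1/2, within
        # a couple of cells' worth of discretisation
        assert abs(hv.proportions["arable"] - 0.5) < 0.05
        assert abs(hv.proportions["forest"] - 0.5) < 0.05

    def test_matches_bruteforce_cell_enumeration(self, landscape):
        point, radius = (4213.0, 5170.0), 2000.0
        hv = extract_buffer_composition(landscape, point, radius)
        # oracle: loop over every cell centre
        n_in, elev_sum = 0, 0.0
        counts = dict.fromkeys(LAND_COVER_CLASSES, 0)
        for r in range(landscape.n_rows):
            for c in range(landscape.n_cols):
                cx, cy = landscape.cell_center(r, c)
                if (cx - point[0]) ** 2 + (cy - point[1]) ** 2 <= radius**2:
                    n_in += 1
                    elev_sum += landscape.elevation[r, c]
                    counts[LAND_COVER_CLASSES[landscape.land_cover[r, c]]] += 1
        assert n_in > 0
        assert hv.elevation == pytest.approx(elev_sum / n_in, abs=1e-9)
        for cls in LAND_COVER_CLASSES:
            assert hv.proportions[cls] == pytest.approx(counts[cls] / n_in, abs=1e-12)

    def test_buffer_off_raster_raises(self, landscape):
        with pytest.raises(ExtractionError):
            extract_buffer_composition(landscape, (-1e6, -1e6), 2000.0)

    def test_edge_buffer_renormalises(self):
        land = _uniform_landscape("water")
        hv = extract_buffer_composition(land, (50.0, 50.0), 2000.0)  # corner
        assert sum(hv.proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestFitNatalPca:
    def test_rank_one_table_explains_everything_on_pc1(self):
        # elevation and one class proportion perfectly correlated; the
        # remaining classes constant (dropped with a warning)
        vecs = []
        for t in np.linspace(0, 1, 8):
            props = dict.fromkeys(LAND_COVER_CLASSES, 0.0)
            props["forest"] = t
            props["arable"] = 1 - t
            vecs.append(HabitatVector(elevation=500 + 400 * t, proportions=props))
        with pytest.warns(UserWarning, match="zero-variance"):
            pca = fit_natal_pca(vecs)
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_vectors_rejected(self):
        props = dict.fromkeys(LAND_COVER_CLASSES, 0.0)
        props["forest"] = 1.0
        vecs = [HabitatVector(600.0, dict(props)) for _ in range(5)]
        with pytest.raises(ValueError):
            fit_natal_pca(vecs)

    def test_matches_direct_eigendecomposition(self, rng):
        vecs = _random_vectors(rng)
        pca = fit_natal_pca(vecs)
        # orthonormal loadings
        G = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)
        # fractions sum to 1 over all axes, non-increasing
        assert pca.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.explained_variance_fraction) <= 1e-12)
        # eigenvalues of the correlation matrix, independently
        X = np.array([v.as_array() for v in vecs])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        lam = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.T)))[::-1]
        np.testing.assert_allclose(
            pca.explained_variance_fraction, lam / lam.sum(), atol=1e-9
        )

    def test_matches_sklearn_scores(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        vecs = _random_vectors(rng)
        pca = fit_natal_pca(vecs)
        X = np.array([v.as_array() for v in vecs])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sklearn.PCA(n_components=2).fit(Z)
        ours = np.array([pca.project(v) for v in vecs])
        theirs = ref.transform(Z)
        for j in range(2):  # axes agree up to sign
            assert min(
                np.abs(ours[:, j] - theirs[:, j]).max(),
                np.abs(ours[:, j] + theirs[:, j]).max(),
            ) < 1e-8


class TestProject:
    def test_mean_vector_scores_zero(self, rng):
        vecs = _random_vectors(rng)
        pca = fit_natal_pca(vecs)
        np.testing.assert_allclose(pca.project(pca.means), 0.0, atol=1e-9)

    def test_training_vector_reproduces_training_score(self, rng):
        vecs = _random_vectors(rng)
        pca = fit_natal_pca(vecs)
        X = np.array([v.as_array() for v in vecs])
        scores = ((X - pca.means) / pca.sds) @ pca.loadings[:, :2]
        for v, s in zip(vecs, scores):
            np.testing.assert_allclose(pca.project(v), s, atol=1e-9)

    def test_hand_built_two_variable_model(self):
        from nhpikit.natal import PCAModel

        pca = PCAModel(
            variable_names=("a", "b"),
            means=np.zeros(2),
            sds=np.ones(2),
            loadings=np.array([[1, 1], [1, -1]]) / np.sqrt(2),
            explained_variance_fraction=np.array([0.8, 0.2]),
            k_retained=1,
        )
        assert pca.project(np.array([1.0, 1.0]))[0] == pytest.approx(np.sqrt(2))


def _bruteforce_complete_linkage(points, k):
    """O(n^3) agglomerative oracle with complete linkage."""
    clusters = [[i] for i in range(len(points))]
    d = np.hypot(*(points[:, None, :] - points[None, :, :]).T).T
    while len(clusters) > k:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(len(points), dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


def _same_partition(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestClusterNatalHabitats:
    def test_separated_clouds_recovered(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]])
        pts = np.vstack([c + 0.01 * rng.standard_normal((6, 2)) for c in centers])
        labels, heights = cluster_natal_habitats(pts, k=4)
        truth = np.repeat(np.arange(4), 6)
        assert _same_partition(labels, truth)
        assert np.all(np.diff(heights) >= -1e-12)  # monotone merges

    def test_k_equals_n_gives_singletons(self, rng):
        pts = rng.standard_normal((7, 2))
        labels, _ = cluster_natal_habitats(pts, k=7)
        assert len(set(labels)) == 7

    def test_hand_traceable_six_points(self):
        # two tight triads far apart: complete linkage must split them
        pts = np.array([[0, 0], [1, 0], [0.5, 1], [20, 0], [21, 0], [20.5, 1]])
        labels, _ = cluster_natal_habitats(pts, k=2)
        assert _same_partition(labels, [0, 0, 0, 1, 1, 1])

    @pytest.mark.parametrize("n,k", [(8, 2), (10, 3), (12, 4)])
    def test_agrees_with_bruteforce_oracle(self, rng, n, k):
        pts = rng.standard_normal((n, 2)) * 3
        labels, _ = cluster_natal_habitats(pts, k=k)
        oracle = _bruteforce_complete_linkage(pts, k)
        assert _same_partition(labels, oracle)

    def test_auto_k_finds_obvious_structure(self, rng):
        centers = np.array([[0, 0], [12, 0], [6, 12]])
        pts = np.vstack([c + 0.05 * rng.standard_normal((8, 2)) for c in centers])
        labels, _ = cluster_natal_habitats(pts, k="auto")
        assert len(set(labels)) == 3

    def test_labels_ordered_by_cluster_size(self, rng):
        pts = np.vstack(
            [np.zeros((8, 2)) + 0.01 * rng.standard_normal((8, 2)),
             np.full((3, 2), 10.0) + 0.01 * rng.standard_normal((3, 2))]
        )
        labels, _ = cluster_natal_habitats(pts, k=2)
        assert (labels[:8] == 0).all() and (labels[8:] == 1).all()

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            cluster_natal_habitats(np.array([[0.0, 0.0]]), k=2)


class TestSignFlipInvariance:
    def test_dissimilarity_and_clusters_unchanged_by_axis_negation(self, rng):
        from nhpikit.steps import compute_dissimilarity

        vecs = _random_vectors(rng)
        pca = fit_natal_pca(vecs)
        flipped = fit_natal_pca(vecs)
        flipped.loadings = flipped.loadings.copy()
        flipped.loadings[:, 0] *= -1  # negate PC1
        a = np.array([pca.project(v) for v in vecs])
        b = np.array([flipped.project(v) for v in vecs])
        # pairwise dissimilarities identical
        for i in range(3):
            for j in range(3, 6):
                assert compute_dissimilarity(pca, a[i], a[j]) == pytest.approx(
                    float(compute_dissimilarity(flipped, b[i], b[j])), abs=1e-12
                )
        la, _ = cluster_natal_habitats(a, k=3)
        lb, _ = cluster_natal_habitats(b, k=3)
        assert _same_partition(la, lb)


class TestScoreGrid:
    def test_matches_exact_extraction_at_cell_centres(self, landscape, natal_stage, score_grid):
        _, pca = natal_stage
        rng = np.random.default_rng(0)
        for _ in range(10):
            r = rng.integers(0, landscape.n_rows)
            c = rng.integers(0, landscape.n_cols)
            cx, cy = landscape.cell_center(r, c)
            hv = extract_buffer_composition(landscape, (float(cx), float(cy)), 2000.0)
            exact = pca.project(hv)
            np.testing.assert_allclose(
                [score_grid.pc1[r, c], score_grid.pc2[r, c]], exact, atol=1e-8
            )
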