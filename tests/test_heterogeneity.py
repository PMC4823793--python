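import numpy as np
import pytest

from ishquant.errors import AnalysisError, HeterogeneityError
from ishquant.heterogeneity import (
    CoreFeatureVector,
    FEATURE_ORDER,
    HeterogeneityParams,
    LocalDistributions,
    MixtureModel,
    compute_rlr_rld,
    confidence_ellipse,
    core_features,
    embed_pca,
    identify_reference_component,
    mahalanobis_distances,
    perturbation_ellipses,
    sample_anchor_points,
    select_k_by_aic,
    snap_without_replacement,
    summarize_features,
    uniform_tissue_draws,
)
from ishquant.points import SignalLabel, SignalPoint
from ishquant.raster import TissueMask


def _cep(x, y):
    return SignalPoint(x, y, 4.0, label=SignalLabel.CEP)


def _gene(x, y):
    return SignalPoint(x, y, 4.0, label=SignalLabel.GENE)


def _full_mask(h=512, w=512):
    return TissueMask(np.ones((h, w), dtype=bool))


class TestAnchors:
    def test_fewer_ceps_than_draws_uses_all_ceps(self):
        pts = [_cep(10 * i, 10 * i) for i in range(5)] + [_gene(3, 3)]
        anchors = sample_anchor_points(pts, _full_mask(), HeterogeneityParams(n_random=300))
        assert len(anchors) == 5

    def test_no_cep_raises(self):
        with pytest.raises(HeterogeneityError):
            sample_anchor_points([_gene(1, 1)], _full_mask(), HeterogeneityParams())

    def test_seeded_determinism_and_distinctness(self):
        rng = np.random.default_rng(0)
        pts = [_cep(x, y) for x, y in rng.uniform(0, 512, size=(1000, 2))]
        params = HeterogeneityParams(n_random=300, seed=42)
        a = sample_anchor_points(pts, _full_mask(), params)
        b = sample_anchor_points(pts, _full_mask(), params)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a, axis=0)) == 300  # no CEP anchors twice

    def test_snapping_matches_brute_force_oracle(self, rng):
        # clustered CEPs: snapping-with-removal differs from naive nearest
        cep = np.vstack(
            [rng.normal((50, 50), 5, size=(40, 2)), rng.normal((200, 200), 5, size=(40, 2))]
        )
        draws = rng.uniform(0, 256, size=(60, 2))
        got = snap_without_replacement(draws, cep)

        used = np.zeros(len(cep), dtype=bool)
        want = []
        for d in draws:  # O(n*m) oracle
            dist = np.hypot(*(cep - d).T)
            dist[used] = np.inf
            j = int(np.argmin(dist))
            used[j] = True
            want.append(j)
        np.testing.assert_array_equal(got, np.array(want))

    def test_uniform_draws_respect_mask(self, rng):
        m = np.zeros((128, 128), dtype=bool)
        m[30:60, 40:90] = True
        mask = TissueMask(m)
        draws = uniform_tissue_draws(mask, 200, rng)
        assert mask.contains(draws[:, 0], draws[:, 1]).all()


class TestLocalStatistics:
    def test_isolated_pairs_give_unit_ratio_density_two(self):
        pts = []
        for i in range(5):
            for j in range(5):
                x, y = 200.0 * i + 30, 200.0 * j + 30  # spacing > 2 x radius
                pts.append(_gene(x + 2, y))
                pts.append(_cep(x, y))
        anchors = np.array([(200.0 * i + 30, 200.0 * j + 30) for i in range(5) for j in range(5)])
        d = compute_rlr_rld(pts, anchors, HeterogeneityParams(radius=60))
        np.testing.assert_allclose(d.rlr, 1.0)
        np.testing.assert_array_equal(d.rld, 2)

    def test_cep_only_core_all_ratios_zero(self):
        pts = [_cep(50.0 * i, 40.0) for i in range(10)]
        anchors = np.array([(50.0 * i, 40.0) for i in range(10)])
        d = compute_rlr_rld(pts, anchors, HeterogeneityParams(radius=60))
        np.testing.assert_allclose(d.rlr, 0.0)

    def test_matches_exhaustive_disk_membership_oracle(self, rng):
        labels = [SignalLabel.GENE, SignalLabel.CEP, SignalLabel.GENE_CEP_MIXED]
        pts = [
            SignalPoint(x, y, 4.0, label=labels[k])
            for x, y, k in zip(
                rng.uniform(0, 500, 500),
                rng.uniform(0, 500, 500),
                rng.integers(0, 3, 500),
            )
        ]
        cepish = [p for p in pts if p.label is not SignalLabel.GENE]
        anchors = np.array([(p.x, p.y) for p in cepish[:100]])
        params = HeterogeneityParams(radius=60)
        d = compute_rlr_rld(pts, anchors, params)
        for i, (ax, ay) in enumerate(anchors):
            g = sum(
                1
                for p in pts
                if p.label is SignalLabel.GENE and np.hypot(p.x - ax, p.y - ay) <= 60
            )
            c = sum(
                1
                for p in pts
                if p.label is SignalLabel.CEP and np.hypot(p.x - ax, p.y - ay) <= 60
            )
            m = sum(
                1
                for p in pts
                if p.label is SignalLabel.GENE_CEP_MIXED
                and np.hypot(p.x - ax, p.y - ay) <= 60
            )
            assert d.rlr[i] == (g + m) / (c + m)
            assert d.rld[i] == g + c + 2 * m


class TestSummaries:
    def test_constant_samples(self):
        d = LocalDistributions(np.ones(10), np.full(10, 2), HeterogeneityParams())
        f = summarize_features(d)
        assert (f.rlr_mean, f.rlr_median, f.rlr_sem) == (1.0, 1.0, 0.0)

    def test_hand_arithmetic(self):
        d = LocalDistributions(
            np.array([0.0, 0.0, 1.0, 1.0]), np.array([1, 1, 2, 2]), HeterogeneityParams()
        )
        f = summarize_features(d)
        assert f.rlr_mean == pytest.approx(0.5)
        assert f.rlr_median == pytest.approx(0.5)
        assert f.rlr_sem == pytest.approx(np.sqrt(1 / 3) / 2)

    def test_duplicating_samples_halves_sem_by_sqrt2(self):
        rlr = np.array([0.2, 0.5, 0.9, 1.1, 0.3])
        rld = np.array([3, 4, 5, 6, 7])
        f1 = summarize_features(LocalDistributions(rlr, rld, HeterogeneityParams()))
        f2 = summarize_features(
            LocalDistributions(np.tile(rlr, 2), np.tile(rld, 2), HeterogeneityParams())
        )
        assert f2.rlr_mean == pytest.approx(f1.rlr_mean)
        assert f2.rlr_median == pytest.approx(f1.rlr_median)
        # duplicated sample SD shrinks slightly (n-1 vs 2n-1), SEM by ~sqrt(2)
        assert f2.rlr_sem == pytest.approx(
            np.std(np.tile(rlr, 2), ddof=1) / np.sqrt(10)
        )
        assert f2.rlr_sem < f1.rlr_sem / 1.3

    def test_too_few_samples_rejected(self):
        with pytest.raises(AnalysisError):
            summarize_features(
                LocalDistributions(np.array([1.0]), np.array([2]), HeterogeneityParams())
            )


def _feat(rlr_mean, seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.1, 1.0, 6)
    vals[0] = rlr_mean
    return CoreFeatureVector(*vals)


class TestPCA:
    def test_single_varying_feature_loads_pc1_fully(self):
        feats = [
            CoreFeatureVector(r, 0.5, 0.1, 8.0, 8.0, 0.3) for r in (0.1, 0.4, 0.7, 1.0)
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = embed_pca(feats)
        assert emb.explained_variance[0] / emb.explained_variance.sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(30, 6)) * np.array([1, 2, 3, 10, 20, 0.5])
        emb = embed_pca(X)
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False))
        order = np.argsort(evals)[::-1][:2]
        V = evecs[:, order]
        for j in range(2):
            i = int(np.argmax(np.abs(V[:, j])))
            if V[i, j] < 0:
                V[:, j] = -V[:, j]
        np.testing.assert_allclose(emb.coords, Z @ V, atol=1e-10)
        np.testing.assert_allclose(emb.explained_variance, evals[order], atol=1e-10)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 6))
        perm = rng.permutation(12)
        a = embed_pca(X)
        b = embed_pca(X[perm])
        np.testing.assert_allclose(a.coords[perm], b.coords, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 6))
        X[:, 2] = 0.7
        with pytest.warns(UserWarning, match="rlr_sem"):
            emb = embed_pca(X)
        assert "rlr_sem" not in emb.kept_features

    def test_project_reproduces_training_coords(self, rng):
        X = rng.normal(size=(15, 6))
        emb = embed_pca(X)
        np.testing.assert_allclose(emb.project(X), emb.coords, atol=1e-10)


class TestModelSelection:
    def test_three_separated_gaussians_select_k3(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 9.0]])
        hits = 0
        for run in range(10):
            comp = rng.integers(0, 3, 71)
            X = centers[comp] + rng.normal(size=(71, 2))
            hits += select_k_by_aic(X, seed=run).k == 3
        assert hits >= 9

    def test_single_gaussian_selects_k1_in_most_draws(self):
        # AIC has an irreducible overselection probability on a true
        # single Gaussian; demand a strong majority, not unanimity
        rng = np.random.default_rng(5)
        ks = [select_k_by_aic(rng.normal(size=(100, 2)), seed=s).k for s in range(10)]
        assert sum(k == 1 for k in ks) >= 8

    def test_k_scan_covers_one_to_five(self, rng):
        X = rng.normal(size=(80, 2))
        m = select_k_by_aic(X, seed=0)
        assert sorted(m.aic_by_k) == [1, 2, 3, 4, 5]

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(AnalysisError):
            select_k_by_aic(rng.normal(size=(5, 2)), k_max=5)


class TestMahalanobis:
    def test_zero_at_mean(self):
        d = mahalanobis_distances([[1.0, 2.0]], [1.0, 2.0], np.eye(2))
        assert d[0] == pytest.approx(0.0)

    def test_identity_covariance_is_euclidean(self):
        d = mahalanobis_distances([[3.0, 4.0]], [0.0, 0.0], np.eye(2))
        assert d[0] == pytest.approx(5.0)

    def test_matches_explicit_inverse_oracle(self, rng):
        A = rng.normal(size=(2, 2))
        cov = A @ A.T + 0.5 * np.eye(2)
        mu = rng.normal(size=2)
        X = rng.normal(size=(40, 2))
        got = mahalanobis_distances(X, mu, cov)
        inv = np.linalg.inv(cov)
        want = np.sqrt(np.einsum("ni,ij,nj->n", X - mu, inv, X - mu))
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_singular_covariance_rejected(self):
        with pytest.raises(AnalysisError):
            mahalanobis_distances([[1.0, 1.0]], [0.0, 0.0], np.zeros((2, 2)))


class TestReferenceComponent:
    def _model(self, assignments, k=3):
        return MixtureModel(
            k=k,
            weights=np.full(k, 1 / k),
            means=np.zeros((k, 2)),
            covariances=np.stack([np.eye(2)] * k),
            aic=0.0,
            assignments=np.asarray(assignments),
            seed=0,
        )

    def test_lowest_mean_rlr_cluster_wins(self):
        feats = [_feat(r, i) for i, r in enumerate([0.2, 0.2, 0.9, 0.9, 0.6, 0.6])]
        model = self._model([0, 0, 1, 1, 2, 2])
        assert identify_reference_component(model, feats) == 0

    def test_tie_goes_to_lower_index(self):
        feats = [_feat(0.5, i) for i in range(4)]
        model = self._model([0, 0, 1, 1], k=2)
        assert identify_reference_component(model, feats) == 0

    def test_empty_component_excluded(self):
        feats = [_feat(r, i) for i, r in enumerate([0.9, 0.9, 0.3, 0.3])]
        model = self._model([1, 1, 2, 2])  # component 0 empty
        assert identify_reference_component(model, feats) == 2


class TestEllipses:
    def test_degenerate_cloud_has_zero_area(self):
        cloud = np.tile([1.0, 2.0], (5, 1))
        e = confidence_ellipse(cloud)
        assert e.area == pytest.approx(0.0)

    def test_ellipse_determinism_and_scaling(self, rng):
        from ishquant.synthetic import generate_point_set, spec_for_prototype

        truth_h = generate_point_set(spec_for_prototype("NON_DELETION", seed=31))
        truth_i = generate_point_set(spec_for_prototype("INTRATUMOUR_HET", seed=32))
        cores = [(truth_h.points, truth_h.mask), (truth_i.points, truth_i.mask)]
        feats = [
            core_features(p, m, HeterogeneityParams(seed=9)) for p, m in cores
        ]
        emb = embed_pca(feats + [core_features(*cores[0], HeterogeneityParams(seed=10))])
        a = perturbation_ellipses(cores, emb, reps=12, base_seed=3)
        b = perturbation_ellipses(cores, emb, reps=12, base_seed=3)
        assert a[0].axes == b[0].axes and a[1].axes == b[1].axes
        # homogeneous core jitters less than the ITH core under resampling
        assert a[0].area < a[1].area
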