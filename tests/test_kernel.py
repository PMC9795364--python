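import numpy as np
import pytest

from spotcorr import (
    DegenerateGeneError,
    EmptyResultError,
    GeneSet,
    InvalidConfigError,
    KernelConfig,
    compute_kernel_weights,
    estimate_region_correlations,
    estimate_spot_covariances,
    estimate_spot_means,
    estimate_spot_variances,
    filter_spots,
    kernel_function,
    pairwise_distances,
)
from conftest import build_dataset, lattice_dataset


def brute_force_weights(ds, config):
    """Independent double-loop computation of region-masked kernel weights."""
    n = ds.n_spots
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if ds.region_labels[i] == ds.region_labels[j]:
                d = np.sqrt(((ds.coordinates[i] - ds.coordinates[j]) ** 2).sum())
                W[i, j] = kernel_function(d, config.family, config.bandwidth)
    return W


class TestKernelFunction:
    @pytest.mark.parametrize("family", ["gaussian", "triangular", "uniform"])
    def test_zero_distance_gives_one(self, family):
        assert kernel_function(0.0, family, 5.0) == pytest.approx(1.0)

    def test_gaussian_unsquared_distance(self):
        # exp(-D/γ), not exp(-D²/γ): at D=γ the weight is exactly e^-1
        assert kernel_function(5.0, "gaussian", 5.0) == pytest.approx(np.exp(-1.0))
        assert kernel_function(10.0, "gaussian", 5.0) == pytest.approx(np.exp(-2.0))

    def test_uniform_boundary_excluded(self):
        assert kernel_function(5.0, "uniform", 5.0) == 0.0
        assert kernel_function(4.999, "uniform", 5.0) == 1.0

    def test_triangular_support(self):
        assert kernel_function(2.0, "triangular", 8.0) == pytest.approx(0.75)
        assert kernel_function(8.0, "triangular", 8.0) == 0.0
        assert kernel_function(12.0, "triangular", 8.0) == 0.0

    def test_invalid_bandwidth(self):
        with pytest.raises(InvalidConfigError):
            kernel_function(1.0, "gaussian", 0.0)


class TestKernelWeights:
    def test_isolated_spot_self_neighbor_only(self):
        ds = build_dataset(n_spots=5, regions=("A", "B", "B", "B", "B"))
        # round-robin assignment puts spot 0 alone in region A only if
        # regions tuple is length 5 with a single A
        ds.region_labels = np.array(["A", "B", "B", "B", "B"], dtype=object)
        D = pairwise_distances(ds)
        w = compute_kernel_weights(ds, D, KernelConfig())
        assert w.effective_neighbors[0] == pytest.approx(1.0)

    def test_coincident_spots_count_twice(self):
        ds = build_dataset(n_spots=2, coords=np.zeros((2, 2)), regions=("A",))
        w = compute_kernel_weights(ds, pairwise_distances(ds), KernelConfig())
        np.testing.assert_allclose(w.effective_neighbors, [2.0, 2.0])

    @pytest.mark.parametrize("family", ["gaussian", "triangular", "uniform"])
    def test_matches_brute_force_on_lattice(self, family):
        ds = lattice_dataset(7, 7, regions=("A", "B"), seed=5)
        cfg = KernelConfig(family=family, bandwidth=5.0)
        w = compute_kernel_weights(ds, pairwise_distances(ds), cfg)
        np.testing.assert_allclose(w.weights, brute_force_weights(ds, cfg), atol=1e-12)
        np.testing.assert_allclose(
            w.effective_neighbors, brute_force_weights(ds, cfg).sum(1), atol=1e-12
        )

    def test_cross_region_weights_zero(self):
        ds = lattice_dataset(5, 5, regions=("A", "B"), seed=2)
        w = compute_kernel_weights(ds, pairwise_distances(ds), KernelConfig())
        diff = ds.region_labels[:, None] != ds.region_labels[None, :]
        assert (w.weights[diff] == 0).all()


class TestFilterSpots:
    def test_two_spot_region_removed_at_default_threshold(self):
        ds = build_dataset(n_spots=2, coords=np.array([[0.0, 0.0], [1.0, 0.0]]))
        w = compute_kernel_weights(ds, pairwise_distances(ds), KernelConfig())
        with pytest.raises(EmptyResultError, match="10"):
            filter_spots(ds, w, 10.0)

    def test_threshold_zero_is_identity(self):
        ds = lattice_dataset(5, 5)
        w = compute_kernel_weights(ds, pairwise_distances(ds), KernelConfig())
        filtered, mask = filter_spots(ds, w, 0.0)
        assert mask.all() and filtered.n_spots == ds.n_spots

    def test_kept_set_matches_brute_force(self):
        ds = lattice_dataset(7, 7)
        cfg = KernelConfig(bandwidth=2.0)
        w = compute_kernel_weights(ds, pairwise_distances(ds), cfg)
        threshold = float(np.median(w.effective_neighbors))  # guarantees a split
        _, mask = filter_spots(ds, w, threshold)
        W = brute_force_weights(ds, cfg)
        np.testing.assert_array_equal(mask, W.sum(1) >= threshold)
        assert mask.any() and not mask.all()  # boundary spots fall below


class TestSpotMoments:
    def setup_method(self):
        self.ds = build_dataset(n_spots=20, n_genes=3, regions=("A", "B"), seed=9)
        self.cfg = KernelConfig(bandwidth=3.0)
        self.w = compute_kernel_weights(self.ds, pairwise_distances(self.ds), self.cfg)

    def test_constant_gene_mean_is_constant(self):
        ds = self.ds
        ds.expression[:, 0] = 3.0
        mu = estimate_spot_means(ds, self.w)
        np.testing.assert_allclose(mu[:, 0], 3.0)

    def test_single_spot_region_mean_is_own_value(self):
        ds = build_dataset(n_spots=3, regions=("A",))
        ds.region_labels = np.array(["A", "A", "solo"], dtype=object)
        w = compute_kernel_weights(ds, pairwise_distances(ds), self.cfg)
        mu = estimate_spot_means(ds, w)
        np.testing.assert_allclose(mu[2], ds.expression[2])
        var = estimate_spot_variances(ds, w, mu)
        np.testing.assert_allclose(var[2], 0.0, atol=1e-15)

    def test_means_match_brute_force(self):
        mu = estimate_spot_means(self.ds, self.w)
        ds, W = self.ds, self.w.weights
        for i in range(ds.n_spots):
            expected = (W[i][:, None] * ds.expression).sum(0) / W[i].sum()
            np.testing.assert_allclose(mu[i], expected, atol=1e-10)

    def test_variances_match_brute_force_own_mean_residuals(self):
        mu = estimate_spot_means(self.ds, self.w)
        var = estimate_spot_variances(self.ds, self.w, mu)
        ds, W = self.ds, self.w.weights
        for i in range(ds.n_spots):
            resid2 = (ds.expression - mu) ** 2  # residual against μ_j, per spot j
            expected = (W[i][:, None] * resid2).sum(0) / W[i].sum()
            np.testing.assert_allclose(var[i], expected, atol=1e-10)

    def test_covariances_match_brute_force_and_are_psd(self):
        mu = estimate_spot_means(self.ds, self.w)
        cov = estimate_spot_covariances(self.ds, self.w, mu)
        ds, W = self.ds, self.w.weights
        resid = ds.expression - mu
        for i in range(ds.n_spots):
            expected = np.einsum("j,jk,jl->kl", W[i], resid, resid) / W[i].sum()
            np.testing.assert_allclose(cov[i], expected, atol=1e-10)
        assert (np.linalg.eigvalsh(cov)[:, 0] >= -1e-10).all()
        var = estimate_spot_variances(self.ds, self.w, mu)
        np.testing.assert_allclose(np.diagonal(cov, axis1=1, axis2=2), var, atol=1e-10)

    def test_duplicated_gene_gives_unit_correlation(self):
        ds = self.ds
        ds.expression[:, 1] = ds.expression[:, 0]
        mu = estimate_spot_means(ds, self.w)
        cov = estimate_spot_covariances(ds, self.w, mu)
        np.testing.assert_allclose(cov[:, 0, 1], cov[:, 0, 0], atol=1e-10)

    def test_constant_gene_raises_degenerate_at_covariance(self):
        ds = self.ds
        ds.expression[:, 2] = 1.0
        mu = estimate_spot_means(ds, self.w)
        with pytest.raises(DegenerateGeneError):
            estimate_spot_covariances(ds, self.w, mu)

    def test_bandwidth_limit_recovers_region_moments(self):
        # γ→∞ within one region: kernel moments → uniform-weight moments
        ds = build_dataset(n_spots=15, n_genes=2, regions=("A",), seed=4)
        cfg = KernelConfig(bandwidth=1e9)
        w = compute_kernel_weights(ds, pairwise_distances(ds), cfg)
        mu = estimate_spot_means(ds, w)
        var = estimate_spot_variances(ds, w, mu)
        np.testing.assert_allclose(mu, np.tile(ds.expression.mean(0), (15, 1)), atol=1e-6)
        np.testing.assert_allclose(
            var, np.tile(ds.expression.var(0), (15, 1)), atol=1e-6
        )

    def test_masking_estimates_ignore_other_regions(self):
        ds = build_dataset(n_spots=20, n_genes=2, regions=("A", "B"), seed=10)
        w = compute_kernel_weights(ds, pairwise_distances(ds), self.cfg)
        mu1 = estimate_spot_means(ds, w)
        idx_b = ds.region_indices("B")
        ds.expression[idx_b] += 100.0
        mu2 = estimate_spot_means(ds, w)
        idx_a = ds.region_indices("A")
        np.testing.assert_allclose(mu1[idx_a], mu2[idx_a], atol=1e-12)


class TestRegionCorrelations:
    def test_duplicate_and_negated_genes(self):
        ds = build_dataset(n_spots=12, n_genes=3, regions=("A",), seed=6)
        ds.expression[:, 1] = ds.expression[:, 0]
        ds.expression[:, 2] = -ds.expression[:, 0]
        rc = estimate_region_correlations(ds)
        R = rc.per_region["A"]
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_matches_textbook_formula(self):
        ds = build_dataset(n_spots=30, n_genes=3, regions=("A",), seed=8)
        R = estimate_region_correlations(ds).per_region["A"]
        Y = ds.expression
        for g in range(3):
            for h in range(3):
                yg, yh = Y[:, g], Y[:, h]
                num = ((yg - yg.mean()) * (yh - yh.mean())).sum()
                den = np.sqrt(((yg - yg.mean()) ** 2).sum() * ((yh - yh.mean()) ** 2).sum())
                assert R[g, h] == pytest.approx(num / den, abs=1e-10)

    def test_degenerate_gene_named_in_error(self):
        ds = build_dataset(n_spots=10, n_genes=2, regions=("A",))
        ds.expression[:, 1] = 7.0
        with pytest.raises(DegenerateGeneError, match="G1"):
            estimate_region_correlations(ds)

    def test_too_few_spots_rejected(self):
        ds = build_dataset(n_spots=2, regions=("A",))
        with pytest.raises(InvalidConfigError, match="3"):
            estimate_region_correlations(ds)

    def test_region_pair_scope_includes_pooled(self):
        ds = build_dataset(n_spots=20, n_genes=2, regions=("A", "B"), seed=3)
        rc = estimate_region_correlations(ds, scope="region-pair", regions=["A", "B"])
        assert set(rc.per_region) == {"A", "B"}
        assert rc.global_ is not None
        np.testing.assert_allclose(np.diag(rc.global_), 1.0)
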