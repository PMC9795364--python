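import itertools

import numpy as np
import pytest

from spotcorr import (
    EmptyResultError,
    GeneSet,
    KernelConfig,
    NotTestableError,
    SMCConfig,
    benjamini_hochberg,
    center_and_permute_residuals,
    compute_kernel_weights,
    pairwise_distances,
    permute_within_regions,
    rank_gene_pairs,
    run_br_test,
    run_wr_test,
    smc_pvalue,
)
from spotcorr.inference import center_residuals, preprocess
from spotcorr.likelihood import WRStatisticEngine
from conftest import build_dataset


def row_multiset(Y):
    return sorted(map(tuple, np.round(Y, 12)))


class TestPermutationSchemes:
    def test_single_spot_regions_identity(self, rng):
        ds = build_dataset(n_spots=4, n_genes=2)
        ds.region_labels = np.array(["a", "b", "c", "d"], dtype=object)
        out = permute_within_regions(ds, rng)
        np.testing.assert_array_equal(out.expression, ds.expression)

    def test_two_spot_region_has_two_arrangements(self):
        ds = build_dataset(n_spots=2, n_genes=2, regions=("A",))
        seen = set()
        for seed in range(20):
            out = permute_within_regions(ds, np.random.default_rng(seed))
            seen.add(tuple(out.expression.ravel()))
        assert len(seen) == 2

    def test_within_region_multisets_preserved(self, rng):
        ds = build_dataset(n_spots=21, n_genes=3, regions=("A", "B", "C"), seed=2)
        out = permute_within_regions(ds, rng)
        for r in ("A", "B", "C"):
            idx = ds.region_indices(r)
            assert row_multiset(out.expression[idx]) == row_multiset(ds.expression[idx])
        np.testing.assert_array_equal(out.region_labels, ds.region_labels)
        np.testing.assert_array_equal(out.coordinates, ds.coordinates)

    def test_centering_zeroes_region_means(self):
        ds = build_dataset(n_spots=20, n_genes=2, regions=("A", "B"), seed=3)
        Yc = center_residuals(ds, ["A", "B"])
        labels = ds.region_labels
        for r in ("A", "B"):
            np.testing.assert_allclose(Yc[labels == r].mean(0), 0.0, atol=1e-12)

    def test_residual_multiset_preserved_across_scope(self, rng):
        ds = build_dataset(n_spots=20, n_genes=2, regions=("A", "B"), seed=4)
        Yc = center_residuals(ds, ["A", "B"])
        out = center_and_permute_residuals(ds, ["A", "B"], rng)
        assert row_multiset(out.expression) == row_multiset(Yc)

    def test_single_zero_mean_region_is_pure_shuffle(self, rng):
        ds = build_dataset(n_spots=10, n_genes=2, regions=("A",), seed=5)
        ds.expression -= ds.expression.mean(0)
        out = center_and_permute_residuals(ds, ["A"], rng)
        assert row_multiset(out.expression) == row_multiset(ds.expression)


class TestSMCPvalue:
    def setup_method(self):
        self.cfg = SMCConfig(exceedance_target=20, max_permutations=10_000, seed=0)

    def test_twentieth_exceedance_at_400_gives_005(self):
        seq = np.zeros(600)
        seq[np.linspace(19, 399, 20, dtype=int)] = 2.0
        pos = [0]

        def sampler(k):
            out = seq[pos[0] : pos[0] + k]
            pos[0] += k
            return np.pad(out, (0, k - len(out)))

        p, l = smc_pvalue(1.0, sampler, self.cfg)
        assert (p, l) == (0.05, 400)

    def test_immediate_exceedances_give_one(self):
        p, l = smc_pvalue(1.0, lambda k: np.full(k, 9.0), self.cfg)
        assert (p, l) == (1.0, 20)

    def test_cap_with_no_exceedance(self):
        p, l = smc_pvalue(1.0, lambda k: np.zeros(k), self.cfg)
        assert p == pytest.approx(1e-4)
        assert l == 9_999

    def test_ties_count_as_exceedances(self):
        p, _ = smc_pvalue(1.0, lambda k: np.ones(k), self.cfg)
        assert p == 1.0

    def test_converges_to_plain_monte_carlo(self):
        # with unlimited budget the SMC estimate concentrates on the true
        # exceedance probability
        true_p = 0.3
        rng = np.random.default_rng(0)
        cfg = SMCConfig(exceedance_target=500, max_permutations=100_000, seed=0)
        p, _ = smc_pvalue(1.0 - true_p, lambda k: rng.uniform(size=k), cfg)
        assert p == pytest.approx(true_p, abs=0.05)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_matches_brute_force(self, rng):
        p = rng.uniform(size=15)
        m = p.size
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        np.testing.assert_allclose(benjamini_hochberg(p), q, atol=1e-12)


def tiny_single_region(n=4, seed=0):
    ds = build_dataset(n_spots=n, n_genes=2, regions=("A",), seed=seed)
    return ds


class TestRunWRTest:
    def test_exhaustive_enumeration_oracle(self):
        # 4 spots, finite bandwidth: SMC over many draws approximates the
        # exact permutation p-value from all 4! arrangements
        ds = tiny_single_region(4, seed=3)
        cfg = KernelConfig(bandwidth=2.0, effective_neighbors_threshold=0.0)
        w = compute_kernel_weights(ds, pairwise_distances(ds), cfg)
        engine = WRStatisticEngine(w.normalized)
        Y = ds.expression
        T_obs = engine(Y)
        exact = np.mean(
            [engine(Y[list(p)]) >= T_obs for p in itertools.permutations(range(4))]
        )
        gs = GeneSet("pair", ["G0", "G1"])
        scfg = SMCConfig(exceedance_target=4000, max_permutations=5001, seed=9)
        res = run_wr_test(ds, gs, cfg, scfg, weights=w)
        assert res.table.p_value[0] == pytest.approx(exact, abs=0.03)

    def test_uniform_weight_limit_is_permutation_invariant(self):
        # γ→∞: every estimate uses uniform weights over the region, so the
        # statistic is the same for every row arrangement
        ds = tiny_single_region(4, seed=5)
        cfg = KernelConfig(bandwidth=1e9, effective_neighbors_threshold=0.0)
        w = compute_kernel_weights(ds, pairwise_distances(ds), cfg)
        engine = WRStatisticEngine(w.normalized)
        Y = ds.expression
        # uniform weights also make the kernel covariance equal the pooled
        # covariance, so null and alternative coincide and T collapses to 0
        for p in itertools.permutations(range(4)):
            assert engine(Y[list(p)]) == pytest.approx(0.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        ds = build_dataset(n_spots=30, n_genes=2, regions=("A", "B"), seed=6)
        cfg = KernelConfig(bandwidth=3.0, effective_neighbors_threshold=0.0)
        scfg = SMCConfig(exceedance_target=10, max_permutations=200, seed=42)
        gs = GeneSet("pair", ["G0", "G1"])
        r1 = run_wr_test(ds, gs, cfg, scfg)
        r2 = run_wr_test(ds, gs, cfg, scfg)
        assert r1.table.equals(r2.table)

    def test_no_testable_region_raises(self):
        ds = build_dataset(n_spots=2, n_genes=2, regions=("A", "B"))
        with pytest.raises(EmptyResultError):
            run_wr_test(
                ds,
                GeneSet("pair", ["G0", "G1"]),
                KernelConfig(effective_neighbors_threshold=0.0),
                SMCConfig(),
            )

    def test_result_has_row_per_region_with_q(self):
        ds = build_dataset(n_spots=30, n_genes=2, regions=("A", "B", "C"), seed=7)
        cfg = KernelConfig(bandwidth=3.0, effective_neighbors_threshold=0.0)
        res = run_wr_test(
            ds,
            GeneSet("pair", ["G0", "G1"]),
            cfg,
            SMCConfig(exceedance_target=5, max_permutations=100, seed=1),
        )
        assert list(res.table.scope) == ["A", "B", "C"]
        assert ((res.table.p_value > 0) & (res.table.p_value <= 1)).all()
        # q-values keep the p-value ordering
        order = np.argsort(res.table.p_value)
        assert (np.diff(res.table.q_value.to_numpy()[order]) >= -1e-12).all()


class TestRunBRTest:
    def _dataset(self, regions=("A", "B", "C"), seed=8):
        return build_dataset(n_spots=45, n_genes=2, regions=regions, seed=seed)

    def _configs(self):
        return (
            KernelConfig(bandwidth=3.0, effective_neighbors_threshold=0.0),
            SMCConfig(exceedance_target=5, max_permutations=100, seed=2),
        )

    def test_pairwise_mode_row_count(self):
        ds = self._dataset()
        kcfg, scfg = self._configs()
        res = run_br_test(ds, GeneSet("pair", ["G0", "G1"]), kcfg, scfg)
        assert len(res.table) == 3  # C(3,2)

    def test_screen_excludes_significant_wr_regions(self):
        ds = self._dataset()
        kcfg, scfg = self._configs()
        gs = GeneSet("pair", ["G0", "G1"])
        wr = run_wr_test(ds, gs, kcfg, scfg)
        wr.table["q_value"] = 1.0
        wr.table.loc[wr.table.scope == "B", "q_value"] = 0.001
        res = run_br_test(ds, gs, kcfg, scfg, wr)
        assert res.excluded_regions == ["B"]
        assert not any("B" in s for s in res.table.scope)

    def test_all_regions_screened_raises(self):
        ds = self._dataset()
        kcfg, scfg = self._configs()
        gs = GeneSet("pair", ["G0", "G1"])
        wr = run_wr_test(ds, gs, kcfg, scfg)
        wr.table["q_value"] = 0.0
        with pytest.raises(NotTestableError):
            run_br_test(ds, gs, kcfg, scfg, wr)

    def test_all_regions_mode_single_row(self):
        ds = self._dataset()
        kcfg, scfg = self._configs()
        res = run_br_test(
            ds, GeneSet("pair", ["G0", "G1"]), kcfg, scfg, mode="all-regions"
        )
        assert len(res.table) == 1
        assert res.table.scope[0] == "A | B | C"

    def test_deterministic_given_seed(self):
        ds = self._dataset(seed=9)
        kcfg, scfg = self._configs()
        gs = GeneSet("pair", ["G0", "G1"])
        r1 = run_br_test(ds, gs, kcfg, scfg)
        r2 = run_br_test(ds, gs, kcfg, scfg)
        assert r1.table.equals(r2.table)


class TestRankGenePairs:
    def test_pair_counts(self):
        ds = build_dataset(n_spots=30, n_genes=4, regions=("A",), seed=10)
        kcfg = KernelConfig(bandwidth=3.0, effective_neighbors_threshold=0.0)
        scfg = SMCConfig(exceedance_target=5, max_permutations=60, seed=3)
        table = rank_gene_pairs(ds, GeneSet("quad", [f"G{i}" for i in range(4)]), "wr", kcfg, scfg)
        assert len(table) == 6
        assert (table.p_value.sort_values().to_numpy() == table.p_value.to_numpy()).all()

    def test_two_genes_single_row(self):
        ds = build_dataset(n_spots=20, n_genes=2, regions=("A",), seed=11)
        kcfg = KernelConfig(bandwidth=3.0, effective_neighbors_threshold=0.0)
        scfg = SMCConfig(exceedance_target=5, max_permutations=60, seed=4)
        table = rank_gene_pairs(ds, GeneSet("pair", ["G0", "G1"]), "wr", kcfg, scfg)
        assert len(table) == 1
        assert (table.gene_a[0], table.gene_b[0]) == ("G0", "G1")
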