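import numpy as np
import pytest

from anscore import (
    ControlConfig,
    ExpressionMatrix,
    GeneSignature,
    MeanExpressionProfile,
    ValidationError,
    bin_genes,
    controls_all_genes,
    controls_ans,
    controls_bin_sampled,
    controls_least_variable,
    exclude_top_expressed,
    mean_expression,
    seurat_dispersion,
)
from anscore.controls import bin_sizes
from conftest import random_matrix


def enumerate_ans_window(tilde_means, c, target):
    """Brute-force argmin over all contiguous windows (leftmost tie)."""
    best_k, best_d = 0, np.inf
    for k in range(len(tilde_means) - c + 1):
        d = abs(target - np.mean(tilde_means[k : k + c]))
        if d < best_d:
            best_k, best_d = k, d
    return best_k


class TestMeanExpression:
    def test_equals_brute_force_column_means(self):
        m = random_matrix(20, 15, seed=3)
        prof = mean_expression(m)
        expected = {g: np.mean(m.dense()[:, j]) for j, g in enumerate(m.gene_ids)}
        for g, mu in zip(prof.gene_ids, prof.means):
            assert mu == pytest.approx(expected[g], rel=1e-12)
        assert np.all(np.diff(prof.means) >= 0)

    def test_all_zero_gene_placed_first(self):
        m = random_matrix(10, 5, seed=1)
        X = m.dense()
        X[:, 3] = 0.0
        m.values = X
        prof = mean_expression(m)
        assert prof.gene_ids[0] == "gene3" and prof.means[0] == 0.0

    def test_exclusion_removes_genes(self):
        m = random_matrix(10, 6, seed=2)
        prof = mean_expression(m, exclude=["gene0", "gene5"])
        assert len(prof) == 4 and "gene0" not in prof.gene_ids

    def test_stable_ties_keep_original_order(self):
        m = ExpressionMatrix(np.ones((4, 5)), [f"c{i}" for i in range(4)],
                             [f"g{j}" for j in range(5)])
        prof = mean_expression(m)
        assert prof.gene_ids == ["g0", "g1", "g2", "g3", "g4"]


class TestBinGenes:
    def test_even_split_100_genes_25_bins(self):
        m = random_matrix(5, 100, seed=4)
        bins = bin_genes(mean_expression(m), 25)
        counts = np.bincount(list(bins.values()))
        assert np.all(counts == 4)

    def test_remainder_goes_to_low_bins(self):
        assert bin_sizes(10, 3) == [4, 3, 3]

    def test_bin_indices_increase_with_expression(self):
        m = random_matrix(8, 30, seed=5)
        prof = mean_expression(m)
        bins = bin_genes(prof, 5)
        assigned = [bins[g] for g in prof.gene_ids]
        assert assigned == sorted(assigned)

    def test_too_many_bins_errors(self):
        m = random_matrix(3, 4)
        with pytest.raises(ValidationError):
            bin_genes(mean_expression(m), 5)


class TestBinSampled:
    def test_controls_in_same_bin_and_not_in_signature(self):
        m = random_matrix(15, 60, seed=6)
        sig = GeneSignature("s", ["gene3", "gene17", "gene42"])
        cfg = ControlConfig(control_size=5, n_bins=6, strategy="bin_sampled", random_seed=9)
        prof = mean_expression(m)
        bins = bin_genes(prof, 6)
        asg = controls_bin_sampled(m, sig, cfg)
        for g in sig.genes:
            assert len(asg.mapping[g]) == 5
            for ctrl in asg.mapping[g]:
                assert bins[ctrl] == bins[g]
                assert ctrl not in sig.genes

    def test_same_seed_identical_assignment(self):
        m = random_matrix(12, 50, seed=7)
        sig = GeneSignature("s", ["gene1", "gene20"])
        cfg = ControlConfig(control_size=4, n_bins=5, strategy="bin_sampled", random_seed=3)
        a = controls_bin_sampled(m, sig, cfg)
        b = controls_bin_sampled(m, sig, cfg)
        assert a.mapping == b.mapping

    def test_bin_of_exactly_c_eligible_genes_is_taken_whole(self):
        m = random_matrix(10, 20, seed=8)
        sig = GeneSignature("s", ["gene0"])
        prof = mean_expression(m)
        bins = bin_genes(prof, 4)  # 5 genes per bin
        eligible = [g for g, b in bins.items() if b == bins["gene0"] and g != "gene0"]
        cfg = ControlConfig(control_size=len(eligible), n_bins=4,
                            strategy="bin_sampled", random_seed=1)
        asg = controls_bin_sampled(m, sig, cfg)
        assert sorted(asg.mapping["gene0"]) == sorted(eligible)

    def test_pooled_variant_shares_one_control_set(self):
        m = random_matrix(10, 60, seed=9)
        sig = GeneSignature("s", ["gene2", "gene40"])
        cfg = ControlConfig(control_size=6, n_bins=6, strategy="bin_sampled",
                            random_seed=2, pooled=True)
        asg = controls_bin_sampled(m, sig, cfg)
        assert asg.mapping["gene2"] == asg.mapping["gene40"]
        assert len(asg.mapping["gene2"]) == 6


class TestAllGenes:
    def test_union_of_controls_is_touched_bins_minus_signature(self):
        m = random_matrix(10, 40, seed=10)
        sig = GeneSignature("s", ["gene5", "gene6", "gene30"])
        cfg = ControlConfig(n_bins=4, strategy="bin_all_genes")
        bins = bin_genes(mean_expression(m), 4)
        asg = controls_all_genes(m, sig, cfg)
        touched = {bins[g] for g in sig.genes}
        expected = {g for g, b in bins.items() if b in touched} - set(sig.genes)
        got = set().union(*(asg.mapping[g] for g in sig.genes))
        assert got == expected

    def test_each_gene_gets_full_bin_minus_signature(self):
        m = random_matrix(10, 40, seed=11)
        sig = GeneSignature("s", ["gene12"])
        cfg = ControlConfig(n_bins=5, strategy="bin_all_genes")
        bins = bin_genes(mean_expression(m), 5)
        asg = controls_all_genes(m, sig, cfg)
        expected = [g for g, b in bins.items() if b == bins["gene12"] and g != "gene12"]
        assert sorted(asg.mapping["gene12"]) == sorted(expected)


class TestLeastVariable:
    def test_matches_brute_force_raw_dispersion_sort(self):
        m = random_matrix(25, 40, seed=12)
        sig = GeneSignature("s", ["gene8", "gene22"])
        cfg = ControlConfig(control_size=3, n_bins=4, strategy="bin_least_variable",
                            use_normalized_dispersion=False)
        asg = controls_least_variable(m, sig, cfg)
        # independent recomputation: variance/mean of expm1 values per gene
        X = np.expm1(m.dense())
        disp = {g: np.var(X[:, j], ddof=1) / np.mean(X[:, j])
                for j, g in enumerate(m.gene_ids)}
        bins = bin_genes(mean_expression(m), 4)
        for g in sig.genes:
            eligible = [x for x, b in bins.items() if b == bins[g] and x not in sig.genes]
            expected = sorted(eligible, key=lambda x: disp[x])[:3]
            assert sorted(asg.mapping[g]) == sorted(expected)

    def test_constant_gene_ranks_first(self):
        m = random_matrix(10, 12, seed=13)
        X = m.dense()
        mid = mean_expression(m).gene_ids[5]  # keep it away from bin edges
        j = m.gene_ids.index(mid)
        X[:, j] = X[:, j].mean()  # constant, same mean -> same bin position
        m.values = X
        disp = seurat_dispersion(m, normalized=True)
        assert disp[mid] == -np.inf

    def test_normalized_dispersion_matches_scanpy(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata

        m = random_matrix(60, 80, seed=14, sparsity=0.3)
        ad = anndata.AnnData(m.dense())
        ad.var_names = m.gene_ids
        scanpy.pp.highly_variable_genes(ad, flavor="seurat", n_bins=20)
        ours = seurat_dispersion(m, normalized=True).to_numpy()
        theirs = ad.var["dispersions_norm"].to_numpy()
        ok = np.isfinite(ours) & np.isfinite(theirs)
        assert ok.sum() > 60
        np.testing.assert_allclose(ours[ok], theirs[ok], rtol=1e-6, atol=1e-6)


class TestExcludeTopExpressed:
    def _matrix_with_ranks(self, p=200, seed=15):
        # strictly increasing means: gene j has mean ~ j
        rng = np.random.default_rng(seed)
        X = np.tile(np.arange(p, dtype=float), (5, 1)) + rng.normal(0, 1e-6, (5, p))
        X -= X.min()
        return ExpressionMatrix(X, [f"c{i}" for i in range(5)],
                                [f"g{j}" for j in range(p)])

    def test_gene_ranked_30th_highest_excluded_at_c100(self):
        m = self._matrix_with_ranks()
        gene = "g170"  # rank 30 from the top of 200
        sig = GeneSignature("s", [gene, "g0"])
        retained, excluded = exclude_top_expressed(sig, m, ControlConfig(control_size=100))
        assert gene in [g for g, _ in excluded]
        assert retained.genes == ["g0"]

    def test_gene_ranked_51st_highest_retained_at_c100(self):
        m = self._matrix_with_ranks()
        gene = "g149"  # rank 51 from the top: just outside floor(c/2)=50
        sig = GeneSignature("s", [gene])
        retained, excluded = exclude_top_expressed(sig, m, ControlConfig(control_size=100))
        assert retained.genes == [gene] and excluded == []

    def test_c2_forbids_only_highest_gene(self):
        m = self._matrix_with_ranks()
        sig = GeneSignature("s", ["g199", "g198"])
        retained, excluded = exclude_top_expressed(sig, m, ControlConfig(control_size=2))
        assert [g for g, _ in excluded] == ["g199"]
        assert retained.genes == ["g198"]

    def test_all_excluded_raises_with_remedy(self):
        m = self._matrix_with_ranks()
        sig = GeneSignature("s", ["g199", "g195"])
        with pytest.raises(ValidationError, match="adjust.*signature|control"):
            exclude_top_expressed(sig, m, ControlConfig(control_size=100))


class TestControlsAns:
    def test_worked_window_example(self):
        # non-signature means (0.0, 0.1, 0.2, 0.9, 1.0), c=2, target 0.16:
        # window means are 0.05, 0.15, 0.55, 0.95 -> argmin |0.16 - w| is {0.1, 0.2}
        means = {"a": 0.0, "b": 0.1, "c": 0.2, "d": 0.9, "e": 1.0, "s": 0.16}
        genes = list(means)
        X = np.tile([means[g] for g in genes], (4, 1))
        m = ExpressionMatrix(X, [f"c{i}" for i in range(4)], genes)
        cfg = ControlConfig(control_size=2, strategy="ans")
        asg = controls_ans(m, GeneSignature("s", ["s"]), cfg)
        assert asg.mapping["s"] == ["b", "c"]

    def test_lowest_gene_gets_first_window(self):
        rng = np.random.default_rng(16)
        X = np.tile(np.linspace(1.0, 2.0, 30), (3, 1)) + rng.normal(0, 1e-9, (3, 30))
        X -= X.min()
        m = ExpressionMatrix(X, ["c0", "c1", "c2"], [f"g{j}" for j in range(30)])
        cfg = ControlConfig(control_size=5, strategy="ans")
        asg = controls_ans(m, GeneSignature("s", ["g0"]), cfg)
        tilde = [g for g in mean_expression(m).gene_ids if g != "g0"]
        assert asg.mapping["g0"] == tilde[:5]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(30, 120))
        mgenes = int(rng.integers(1, 8))
        c = int(rng.integers(2, 15))
        m = random_matrix(10, p, seed=seed + 1000)
        sig_genes = [m.gene_ids[i] for i in rng.choice(p, mgenes, replace=False)]
        cfg = ControlConfig(control_size=c, strategy="ans")
        sig = GeneSignature("s", sig_genes)
        try:
            asg = controls_ans(m, sig, cfg)
        except ValidationError:
            return  # whole signature in exclusion zone: checked elsewhere
        prof = mean_expression(m)
        tilde = [(g, mu) for g, mu in zip(prof.gene_ids, prof.means) if g not in sig_genes]
        tilde_genes = [g for g, _ in tilde]
        tilde_means = np.array([mu for _, mu in tilde])
        gmean = dict(zip(prof.gene_ids, prof.means))
        for g in asg.retained_signature_genes:
            k = enumerate_ans_window(tilde_means, c, gmean[g])
            assert asg.mapping[g] == tilde_genes[k : k + c]

    def test_window_means_are_nondecreasing(self):
        m = random_matrix(8, 100, seed=17)
        prof = mean_expression(m)
        c = 10
        csum = np.concatenate([[0.0], np.cumsum(prof.means)])
        wmeans = (csum[c:] - csum[:-c]) / c
        assert np.all(np.diff(wmeans) >= -1e-12)

    def test_control_size_exceeding_gene_pool_errors(self):
        m = random_matrix(5, 10, seed=18)
        cfg = ControlConfig(control_size=10, strategy="ans")
        with pytest.raises(ValidationError, match="exceeds"):
            controls_ans(m, GeneSignature("s", ["gene0"]), cfg)


def test_no_strategy_puts_signature_genes_in_controls():
    m = random_matrix(20, 80, seed=19)
    sig = GeneSignature("s", ["gene4", "gene33", "gene60"])
    for strategy, fn in [
        ("ans", controls_ans),
        ("bin_sampled", controls_bin_sampled),
        ("bin_all_genes", controls_all_genes),
        ("bin_least_variable", controls_least_variable),
    ]:
        cfg = ControlConfig(control_size=6, n_bins=5, strategy=strategy, random_seed=0)
        asg = fn(m, sig, cfg)
        for g, ctrls in asg.mapping.items():
            assert not set(ctrls) & set(sig.genes)
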