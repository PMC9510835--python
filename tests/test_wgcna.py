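import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from coexmark import simulate, wgcna
from oracles import brute_tom


def _frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


class TestScaleFreeFit:
    def test_inverse_power_law_scores_plus_one(self):
        # bin frequencies exactly proportional to 1/k at bin means 1,2,4,8
        k = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])
        r2, slope = wgcna.scale_free_fit(k, n_bins=8)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert slope == pytest.approx(-1.0, abs=1e-6)

    def test_increasing_power_law_scores_minus_one(self):
        # frequencies proportional to k^2 -> positive slope flips the index
        k = np.repeat([1.0, 2.0, 4.0, 8.0], [1, 4, 16, 64])
        r2, slope = wgcna.scale_free_fit(k, n_bins=8)
        assert r2 == pytest.approx(-1.0, abs=1e-6)
        assert slope == pytest.approx(2.0, abs=1e-6)

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError, match="all connectivities equal"):
            wgcna.scale_free_fit(np.full(50, 3.0))


class TestAdjacency:
    def test_unsigned_values(self):
        cor = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = wgcna.adjacency(cor, 1)
        assert adj[0, 1] == 0.5
        assert adj[0, 0] == 0.0  # diagonal zeroed for connectivity sums

    def test_perfect_correlation_stays_one(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 5, 14):
            assert wgcna.adjacency(cor, beta)[0, 1] == 1.0

    def test_power_two_squares_power_one(self):
        rng = np.random.default_rng(0)
        cor = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        a1 = wgcna.adjacency(cor, 1)
        a2 = wgcna.adjacency(cor, 2)
        assert np.allclose(a2, a1**2)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            wgcna.adjacency(np.eye(2), 0.5)


class TestTOM:
    def test_isolated_perfect_pair(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = wgcna.tom_similarity(adj)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_gives_identity(self):
        tom = wgcna.tom_similarity(np.zeros((5, 5)))
        assert np.array_equal(tom, np.eye(5))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(11)
        adj = rng.uniform(0, 1, (6, 6))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        assert np.allclose(wgcna.tom_similarity(adj), brute_tom(adj), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        adj = rng.uniform(0, 1, (15, 15))
        adj = (adj + adj.T) / 2
        tom = wgcna.tom_similarity(adj)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
        assert np.allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1.0)


def _brute_force_scan(matrix, powers, r2_cut=0.9, n_bins=10):
    """Cell-by-cell reimplementation of the soft-threshold scan."""
    genes = list(matrix.index)
    n = len(genes)
    cor = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            r = stats.pearsonr(matrix.iloc[i], matrix.iloc[j])[0] if i != j else 1.0
            cor[i, j] = cor[j, i] = r
    results = []
    for beta in powers:
        k = np.array(
            [sum(abs(cor[i, j]) ** beta for j in range(n) if j != i) for i in range(n)]
        )
        try:
            r2, _ = wgcna.scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        results.append(r2)
    for beta, r2 in zip(powers, results):
        if np.isfinite(r2) and r2 >= r2_cut:
            return beta
    finite = [(r2, b) for b, r2 in zip(powers, results) if np.isfinite(r2)]
    return max(finite)[1]


class TestPickSoftThreshold:
    def test_matches_brute_force_on_noise(self, random_matrix):
        matrix = random_matrix(120, 30, seed=1)
        powers = list(range(1, 11))
        scan = wgcna.pick_soft_threshold(matrix, powers=powers)
        assert scan.chosen_beta == _brute_force_scan(matrix, powers)

    def test_minimality_of_chosen_power(self):
        cfg = simulate.SyntheticConfig(n_genes=300, n_modules=2, module_sizes=(60, 60), seed=1)
        X, _, _ = simulate.generate_expression(cfg)
        scan = wgcna.pick_soft_threshold(X)
        if scan.met_cut:
            for beta, r2 in zip(scan.powers, scan.fit_r2):
                if beta < scan.chosen_beta:
                    assert not (np.isfinite(r2) and r2 >= scan.r2_cut)

    def test_degenerate_all_ones_flagged(self):
        # single noise-free module: every |cor| = 1, connectivity constant
        t = np.linspace(0, 1, 10)
        matrix = _frame(np.outer(np.arange(1, 7), t) + 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            wgcna.pick_soft_threshold(matrix)


class TestDetectModules:
    def _two_block_matrix(self, block=40, samples=30, noise=1e-6, seed=0):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.normal(0, 1, (2, samples))
        rows = [f1 + rng.normal(0, noise, samples) for _ in range(block)]
        rows += [f2 + rng.normal(0, noise, samples) for _ in range(block)]
        return _frame(np.array(rows))

    def test_two_noise_free_blocks_found_exactly(self):
        matrix = self._two_block_matrix()
        cor = np.corrcoef(matrix.to_numpy())
        tom = wgcna.tom_similarity(wgcna.adjacency(cor, 6))
        assignment, eigengenes = wgcna.detect_modules(tom, list(matrix.index), matrix=matrix)
        sizes = assignment.sizes()
        assert sorted(sizes[sizes.index != "grey"]) == [40, 40]
        assert (assignment.colors == "grey").sum() == 0
        assert eigengenes.shape == (30, 2)

    def test_undersized_cluster_goes_grey(self):
        matrix = self._two_block_matrix(block=10)
        cor = np.corrcoef(matrix.to_numpy())
        tom = wgcna.tom_similarity(wgcna.adjacency(cor, 6))
        with pytest.warns(UserWarning):
            assignment, _ = wgcna.detect_modules(
                tom, list(matrix.index), matrix=matrix, min_size=30
            )
        assert (assignment.colors == "grey").all()

    def test_recovers_planted_modules(self):
        cfg = simulate.SyntheticConfig(
            n_genes=560, module_sizes=(100,) * 4, factor_loading=0.9,
            noise_sd=0.5, n_discriminative=0, trait_linked_modules=(), seed=5,
        )
        X, _, truth = simulate.generate_expression(cfg)
        cor = np.corrcoef(X.to_numpy())
        tom = wgcna.tom_similarity(wgcna.adjacency(cor, 6))
        assignment, _ = wgcna.detect_modules(tom, list(X.index), matrix=X)
        planted = {g: m for g, m in truth.module_label_per_gene.items() if m != -1}
        genes = list(planted)
        ari = adjusted_rand_score(
            [planted[g] for g in genes], [assignment.colors[g] for g in genes]
        )
        assert ari >= 0.8

    def test_partition_invariant_to_gene_order(self):
        matrix = self._two_block_matrix(block=35, seed=3)
        rng = np.random.default_rng(1)
        perm = rng.permutation(matrix.index)
        shuffled = matrix.loc[perm]

        def partition(m):
            cor = np.corrcoef(m.to_numpy())
            tom = wgcna.tom_similarity(wgcna.adjacency(cor, 6))
            assignment, _ = wgcna.detect_modules(tom, list(m.index), matrix=m)
            groups = {}
            for gene, color in assignment.colors.items():
                groups.setdefault(color, set()).add(gene)
            return {frozenset(v) for v in groups.values()}

        assert partition(matrix) == partition(shuffled)


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        matrix = _frame(np.tile(profile, (4, 1)))
        me, varexp = wgcna.module_eigengene(matrix)
        assert varexp == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(stats.pearsonr(me, z)[0]) == pytest.approx(1.0)

    def test_sign_convention_follows_mean_profile(self, random_matrix):
        matrix = random_matrix(20, 10, seed=2)
        me, _ = wgcna.module_eigengene(matrix)
        z = ((matrix.T - matrix.mean(axis=1)) / matrix.std(axis=1, ddof=1)).T
        assert np.dot(me, z.mean(axis=0)) >= 0
        me_neg, _ = wgcna.module_eigengene(-matrix)
        z_neg = ((-matrix.T - (-matrix).mean(axis=1)) / (-matrix).std(axis=1, ddof=1)).T
        assert np.dot(me_neg, z_neg.mean(axis=0)) >= 0

    def test_variance_explained_matches_eigendecomposition(self, random_matrix):
        matrix = random_matrix(20, 10, seed=2)
        _, varexp = wgcna.module_eigengene(matrix)
        z = stats.zscore(matrix.to_numpy(), axis=1, ddof=1)
        eigvals = np.linalg.eigvalsh(z @ z.T)
        assert varexp == pytest.approx(eigvals[-1] / eigvals.sum(), abs=1e-10)


class TestModuleTrait:
    def _pheno(self, groups):
        return pd.DataFrame({"group": groups}, index=[f"S{i}" for i in range(len(groups))])

    def test_indicator_eigengene_selected(self):
        groups = ["AS"] * 5 + ["HC"] * 5
        trait = np.array([1.0] * 5 + [0.0] * 5)
        eig = pd.DataFrame({"blue": trait}, index=[f"S{i}" for i in range(10)])
        table = wgcna.module_trait_correlation(eig, self._pheno(groups))
        assert table.loc["blue", "r"] == pytest.approx(1.0)
        assert bool(table.loc["blue", "selected"])

    def test_orthogonal_eigengene_not_selected(self):
        groups = ["AS", "AS", "HC", "HC"]
        eig = pd.DataFrame({"blue": [1.0, -1.0, 1.0, -1.0]}, index=[f"S{i}" for i in range(4)])
        table = wgcna.module_trait_correlation(eig, self._pheno(groups))
        assert table.loc["blue", "r"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(table.loc["blue", "selected"])

    def test_trait_linked_module_attains_max_r(self):
        wins = 0
        for seed in range(1, 21):
            cfg = simulate.SyntheticConfig(
                n_genes=500, module_sizes=(80,) * 4, factor_loading=0.8,
                noise_sd=1.0, n_discriminative=0, trait_linked_modules=(0,),
                factor_trait_shift=1.0, seed=seed,
            )
            X, pheno, truth = simulate.generate_expression(cfg)
            mes = {}
            for m in range(4):
                genes = [g for g, l in truth.module_label_per_gene.items() if l == m]
                mes[f"M{m}"], _ = wgcna.module_eigengene(X.loc[genes])
            table = wgcna.module_trait_correlation(pd.DataFrame(mes), pheno)
            wins += table["r"].abs().idxmax() == "M0"
        assert wins >= 18  # >= 90% of 20 seeds

    def test_constant_eigengene_rejected(self):
        eig = pd.DataFrame({"blue": [1.0, 1.0, 1.0, 1.0]}, index=[f"S{i}" for i in range(4)])
        with pytest.raises(ValueError, match="constant"):
            wgcna.module_trait_correlation(eig, self._pheno(["AS", "AS", "HC", "HC"]))


class TestGeneTraitStats:
    def test_gene_equal_to_eigengene_has_mm_one(self, small_dataset):
        X, pheno, truth = small_dataset
        genes0 = [g for g, m in truth.module_label_per_gene.items() if m == 0]
        me, _ = wgcna.module_eigengene(X.loc[genes0])
        eig = pd.DataFrame({"turquoise": me})
        probe = X.copy()
        probe.loc[genes0[0]] = me.to_numpy()
        gs, mm, _ = wgcna.gene_trait_stats(probe, eig, pheno)
        assert mm.loc[genes0[0], "turquoise"] == pytest.approx(1.0)

    def test_noise_gene_gs_near_zero(self, two_group_phenotypes):
        pheno = two_group_phenotypes(15, 15)
        n = 30
        crit = stats.t.ppf(0.975, n - 2)
        crit_r = crit / np.sqrt(n - 2 + crit**2)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(0, 1, (2, n)), index=["noise", "other"], columns=pheno.index
            )
            eig = pd.DataFrame({"m": rng.normal(0, 1, n)}, index=pheno.index)
            gs, _, _ = wgcna.gene_trait_stats(X, eig, pheno)
            hits += gs["noise"] < crit_r
        assert hits >= 18

    def test_mm_gs_positive_for_trait_linked_module(self, small_dataset):
        X, pheno, truth = small_dataset
        genes0 = [g for g, m in truth.module_label_per_gene.items() if m == 0]
        me, _ = wgcna.module_eigengene(X.loc[genes0])
        eig = pd.DataFrame({"turquoise": me})
        colors = pd.Series(
            ["turquoise" if g in set(genes0) else "grey" for g in X.index], index=X.index
        )
        assignment = wgcna.ModuleAssignment(colors)
        _, _, mm_gs = wgcna.gene_trait_stats(X, eig, pheno, assignment)
        assert mm_gs.loc["turquoise", "cor_mm_gs"] > 0


class TestPreservationZ:
    def test_null_modules_not_preserved(self):
        flagged = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = _frame(rng.normal(0, 1, (60, 20)))
            colors = pd.Series("grey", index=X.index)
            members = rng.choice(X.index, 15, replace=False)
            colors[members] = "blue"
            z = wgcna.preservation_z(
                X, wgcna.ModuleAssignment(colors), n_permutations=50, seed=seed
            )
            flagged += abs(z["blue"]) < 3
        assert flagged >= 45

    def test_planted_module_beats_null_module(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, 20)
        planted = np.array([f + rng.normal(0, 1e-3, 20) for _ in range(15)])
        noise = rng.normal(0, 1, (45, 20))
        X = _frame(np.vstack([planted, noise]))
        colors = pd.Series("grey", index=X.index)
        colors[X.index[:15]] = "blue"
        colors[X.index[15:30]] = "red"  # random genes labeled as a module
        z = wgcna.preservation_z(X, wgcna.ModuleAssignment(colors), n_permutations=100, seed=1)
        assert z["blue"] > 0
        assert z["blue"] > z["red"]

    def test_zero_permutations_rejected(self, small_dataset):
        X, _, _ = small_dataset
        colors = pd.Series("blue", index=X.index)
        with pytest.raises(ValueError):
            wgcna.preservation_z(X, wgcna.ModuleAssignment(colors), n_permutations=0)
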