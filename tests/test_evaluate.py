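import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexmark import evaluate, simulate, wgcna
from oracles import brute_auc


class TestRocAuc:
    def test_perfect_separation(self):
        auc, p = evaluate.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert p < 0.05

    def test_identical_scores_are_uninformative(self):
        auc, p = evaluate.roc_auc([5.0] * 8, [0, 1] * 4)
        assert auc == 0.5
        assert p == 1.0

    def test_hand_examples(self):
        auc, _ = evaluate.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        auc, _ = evaluate.roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert auc == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _ = evaluate.roc_auc(scores, labels)
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 20)
        labels = np.array([0, 1] * 10)
        auc_pos, _ = evaluate.roc_auc(scores, labels)
        auc_neg, _ = evaluate.roc_auc(-scores, labels)
        assert auc_pos + auc_neg == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc([1, 2, 3], [1, 1, 1])


class TestScreenSignificant:
    def _roc(self, ps):
        return pd.DataFrame({"p": ps}, index=[f"G{i}" for i in range(len(ps))])

    def test_all_significant_is_identity(self):
        roc = self._roc([0.001, 0.01, 0.04])
        retained, discarded = evaluate.screen_significant(roc)
        assert retained == list(roc.index) and discarded == []

    def test_boundary_alpha_discarded(self):
        roc = self._roc([0.05])
        retained, discarded = evaluate.screen_significant(roc, alpha=0.05)
        assert retained == [] and discarded == ["G0"]

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        roc = self._roc(rng.uniform(0, 1, 50))
        kept_strict, _ = evaluate.screen_significant(roc, alpha=0.01)
        kept_loose, _ = evaluate.screen_significant(roc, alpha=0.10)
        assert set(kept_strict) <= set(kept_loose)

    def test_null_gene_usually_discarded(self, two_group_phenotypes):
        pheno = two_group_phenotypes(15, 15)
        discarded = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            matrix = pd.DataFrame(
                rng.normal(0, 1, (1, 30)), index=["noise"], columns=pheno.index
            )
            roc = evaluate.roc_table(matrix, pheno, ["noise"])
            discarded += not roc.loc["noise", "significant"]
        assert discarded >= 18


class TestGroupDifference:
    def test_identical_groups_score_zero(self, two_group_phenotypes):
        pheno = two_group_phenotypes(4, 4)
        row = [1.0, 2.0, 3.0, 4.0] * 2
        matrix = pd.DataFrame([row], index=["G0"], columns=pheno.index)
        table = evaluate.group_difference_test(matrix, pheno, ["G0"])
        assert table.loc["G0", "F"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_two_group_f_equals_t_squared(self, seed, random_matrix, two_group_phenotypes):
        matrix = random_matrix(10, 20, seed=seed)
        pheno = two_group_phenotypes(12, 8)
        table = evaluate.group_difference_test(matrix, pheno, list(matrix.index))
        case = matrix.loc[:, pheno.index[pheno["group"] == "AS"]]
        ctrl = matrix.loc[:, pheno.index[pheno["group"] == "HC"]]
        for g in matrix.index:
            t, _ = stats.ttest_ind(case.loc[g], ctrl.loc[g])
            assert table.loc[g, "F"] == pytest.approx(t**2, abs=1e-10)

    def test_planted_shift_detected(self, two_group_phenotypes):
        pheno = two_group_phenotypes(40, 40)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.normal(0, 1, (1, 80))
            values[0, :40] += 1.5
            matrix = pd.DataFrame(values, index=["G0"], columns=pheno.index)
            table = evaluate.group_difference_test(matrix, pheno, ["G0"])
            hits += table.loc["G0", "p"] < 0.01
        assert hits >= 18

    def test_constant_gene_warns_p_one(self, two_group_phenotypes):
        pheno = two_group_phenotypes(3, 3)
        matrix = pd.DataFrame([[2.0] * 6], index=["G0"], columns=pheno.index)
        with pytest.warns(UserWarning, match="constant"):
            table = evaluate.group_difference_test(matrix, pheno, ["G0"])
        assert table.loc["G0", "p"] == 1.0


class TestSeverityCorrelation:
    def _dataset(self, severity, values, n_ctrl=3):
        n_case = len(severity)
        samples = [f"S{i}" for i in range(n_case + n_ctrl)]
        pheno = pd.DataFrame(
            {
                "group": ["AS"] * n_case + ["HC"] * n_ctrl,
                "severity": list(severity) + [np.nan] * n_ctrl,
            },
            index=samples,
        )
        matrix = pd.DataFrame(
            [list(values) + [0.0] * n_ctrl], index=["G0"], columns=samples
        )
        return matrix, pheno

    def test_identical_severity_gives_perfect_r(self):
        sev = [1.0, 4.0, 2.0, 8.0, 5.0]
        matrix, pheno = self._dataset(sev, sev)
        table = evaluate.severity_correlation(matrix, pheno, ["G0"])
        assert table.loc["G0", "r"] == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # x = 1..5 against y = (2,4,5,4,5): r = 0.7746
        matrix, pheno = self._dataset([2.0, 4.0, 5.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        table = evaluate.severity_correlation(matrix, pheno, ["G0"])
        assert table.loc["G0", "r"] == pytest.approx(0.7745966692, abs=1e-9)

    def test_null_coupling_fraction_near_alpha(self):
        cfg = simulate.SyntheticConfig(
            n_genes=100, n_samples_case=40, n_samples_control=10,
            n_modules=0, module_sizes=(), n_discriminative=0,
            trait_linked_modules=(), seed=2,
        )
        X, pheno, _ = simulate.generate_expression(cfg)
        pheno = pheno.copy()
        pheno["severity"] = simulate.generate_severity(
            pheno, X, list(X.index[:1]), coupling=0.0, seed=3
        )
        table = evaluate.severity_correlation(X, pheno, list(X.index))
        n_sig = int(table["significant"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 100, 0.05)
        assert lo <= n_sig <= hi

    def test_too_few_cases_rejected(self):
        matrix, pheno = self._dataset([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="3 cases"):
            evaluate.severity_correlation(matrix, pheno, ["G0"])


class TestRecoveryMetrics:
    def _truth(self):
        truth = simulate.GroundTruth(
            module_label_per_gene={"A": 0, "B": 0, "C": 1, "D": 1, "E": -1},
            discriminative_genes={"A", "C"},
            planted_hubs={"B"},
        )
        return truth

    def test_perfect_outputs_score_one(self):
        truth = self._truth()
        colors = pd.Series(
            {"A": "blue", "B": "blue", "C": "red", "D": "red", "E": "grey"}
        )
        report = evaluate.recovery_metrics(
            truth,
            assignment=wgcna.ModuleAssignment(colors),
            de_genes={"A", "C"},
            hub_genes={"B"},
            key_genes={"A", "C"},
        )
        for key in ("module_ari", "de_precision", "de_recall", "hub_recall",
                    "key_gene_precision", "key_gene_recall"):
            assert report[key] == 1.0

    def test_ari_invariant_to_label_names(self):
        truth = self._truth()
        renamed = pd.Series(
            {"A": "green", "B": "green", "C": "yellow", "D": "yellow", "E": "grey"}
        )
        report = evaluate.recovery_metrics(truth, assignment=wgcna.ModuleAssignment(renamed))
        assert report["module_ari"] == 1.0

    def test_random_key_sets_score_at_planted_fraction(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(100)]
        planted = set(genes[:20])
        truth = simulate.GroundTruth(
            module_label_per_gene={g: -1 for g in genes},
            discriminative_genes=planted,
        )
        precisions = []
        for _ in range(100):
            chosen = set(rng.choice(genes, 10, replace=False))
            report = evaluate.recovery_metrics(truth, key_genes=chosen)
            precisions.append(report["key_gene_precision"])
        assert np.mean(precisions) == pytest.approx(0.2, abs=0.05)

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate.recovery_metrics(None, key_genes={"A"})
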