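"""Correlation matrices, profile clustering, coherence classes, tissue order."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nrf_targetscope import (
    CorrelationMatrix,
    TissueResult,
    analyze_tissue,
    classify_coherence,
    cluster_correlation_profiles,
    correlation_matrix,
    cross_tissue_order,
    simulate_tissue_panel,
)
from nrf_targetscope.differential_expression import ExpressionMatrix

GENES = [f"G{i:03d}" for i in range(60)]


def panel_matrix(values, gene_ids, tissue="brain"):
    n_genes, n_donors = values.shape
    donors = [f"{tissue}_d{i}" for i in range(n_donors)]
    design = pd.DataFrame(
        {"tissue": [tissue] * n_donors, "donor": range(n_donors)},
        index=pd.Index(donors, name="sample"),
    )
    return ExpressionMatrix(gene_ids, donors, values, design)


def block_correlation(n_a=10, n_b=10, r=0.95, seed=0, n_donors=400):
    """Two well-separated planted blocks; returns (matrix, truth labels)."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal((2, n_donors))
    lam = np.sqrt(r / (1 - r))
    rows = [lam * f1 + rng.standard_normal(n_donors) for _ in range(n_a)]
    rows += [lam * f2 + rng.standard_normal(n_donors) for _ in range(n_b)]
    data = 2.0 ** (10 + np.array(rows))
    genes = [f"g{i:02d}" for i in range(n_a + n_b)]
    m = panel_matrix(data, genes)
    return correlation_matrix(m, genes, min_samples=3), [0] * n_a + [1] * n_b


class TestCorrelationMatrix:
    def test_duplicated_gene_profile_correlates_at_one(self):
        rng = np.random.default_rng(0)
        row = 2.0 ** (8 + rng.standard_normal(100))
        m = panel_matrix(np.vstack([row, row, rng.uniform(1, 9, 100)]),
                         ["a", "a_copy", "c"])
        cm = correlation_matrix(m, ["a", "a_copy", "c"], min_samples=3)
        i, j = cm.gene_ids.index("a"), cm.gene_ids.index("a_copy")
        assert cm.values[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_exact_anticorrelation(self):
        # y = -x on the log2(+1) analysis scale
        x = np.linspace(1, 5, 50)
        vals = np.vstack([2.0**x - 1.0, 2.0 ** (-x + 6) - 1.0,
                          np.random.default_rng(1).uniform(1, 9, 50)])
        m = panel_matrix(vals, ["x", "y", "z"])
        cm = correlation_matrix(m, ["x", "y", "z"], min_samples=3)
        i, j = cm.gene_ids.index("x"), cm.gene_ids.index("y")
        assert cm.values[i, j] == pytest.approx(-1.0, abs=1e-12)

    def test_exactly_symmetric_unit_diagonal(self):
        cm, _ = block_correlation(seed=3)
        assert np.array_equal(cm.values, cm.values.T)
        assert (np.diag(cm.values) == 1.0).all()
        assert np.abs(cm.values).max() <= 1.0

    def test_zero_variance_genes_dropped(self, caplog):
        rng = np.random.default_rng(2)
        vals = np.vstack([rng.uniform(1, 9, (3, 40)), np.full((1, 40), 5.0)])
        m = panel_matrix(vals, ["a", "b", "c", "flat"])
        with caplog.at_level("INFO"):
            cm = correlation_matrix(m, ["a", "b", "c", "flat"], min_samples=3)
        assert "flat" not in cm.gene_ids

    def test_too_few_donors_rejected(self):
        m = panel_matrix(np.random.default_rng(0).uniform(1, 9, (4, 5)),
                         ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="donors"):
            correlation_matrix(m, ["a", "b"], min_samples=10)

    def test_planted_within_module_correlation(self):
        panels, truth = simulate_tissue_panel(GENES, n_tissues=1, n_donors=200,
                                              r_within=0.9, seed=17)
        tissue, panel = next(iter(panels.items()))
        cm = correlation_matrix(panel, GENES, min_samples=10)
        labels = truth.module_assignment[tissue]
        idx = [i for i, g in enumerate(cm.gene_ids) if labels[g] == "coherent"]
        sub = cm.values[np.ix_(idx, idx)]
        mean_r = (sub.sum() - len(idx)) / (len(idx) * (len(idx) - 1))
        assert 0.85 <= mean_r <= 0.95


class TestClustering:
    def test_two_separated_blocks_recovered_exactly(self):
        cm, truth = block_correlation()
        labels = cluster_correlation_profiles(cm, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_three_group_planted_structure(self):
        panels, truth = simulate_tissue_panel(GENES, n_tissues=1, n_donors=200,
                                              r_within=0.9, seed=23)
        tissue, panel = next(iter(panels.items()))
        cm = correlation_matrix(panel, GENES, min_samples=10)
        labels = cluster_correlation_profiles(cm, k=3, seed=5)
        true = [truth.module_assignment[tissue][g] for g in cm.gene_ids]
        assert adjusted_rand_score(true, labels) >= 0.9

    def test_deterministic_under_seed(self):
        cm, _ = block_correlation(seed=7)
        l1 = cluster_correlation_profiles(cm, k=2, seed=3)
        l2 = cluster_correlation_profiles(cm, k=2, seed=3)
        assert np.array_equal(l1, l2)

    def test_hierarchical_agrees_on_separable_case(self):
        cm, truth = block_correlation(seed=11)
        labels = cluster_correlation_profiles(cm, k=2, method="hierarchical")
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_permutation_equivariant_on_separable_case(self):
        cm, _ = block_correlation(seed=13)
        perm = np.random.default_rng(4).permutation(len(cm.gene_ids))
        permuted = CorrelationMatrix(
            gene_ids=[cm.gene_ids[i] for i in perm],
            values=cm.values[np.ix_(perm, perm)],
            tissue=cm.tissue,
        )
        base = cluster_correlation_profiles(cm, k=2, seed=1)
        shuf = cluster_correlation_profiles(permuted, k=2, seed=1)
        assert np.array_equal(base[perm], shuf)

    def test_k_not_below_gene_count_rejected(self):
        cm, _ = block_correlation(n_a=2, n_b=2)
        with pytest.raises(ValueError):
            cluster_correlation_profiles(cm, k=4)


class TestCoherenceClasses:
    def test_planted_modules_classified(self):
        panels, truth = simulate_tissue_panel(GENES, n_tissues=1, n_donors=200,
                                              r_within=0.9, seed=29)
        tissue, panel = next(iter(panels.items()))
        tr = analyze_tissue(panel, GENES, seed=2)
        labels = truth.module_assignment[tissue]
        background = []
        for g in tr.matrix.gene_ids:
            if labels[g] == "coherent":
                assert tr.classes[g] == "correlated"
            elif labels[g] == "anti":
                assert tr.classes[g] == "anti-correlated"
            else:
                # mean correlation to core ~ N(0, ~0.07) at 200 donors, so a
                # background gene occasionally dips below tau_neg = -0.1;
                # tau_pos = 0.3 is far out of reach
                assert tr.classes[g] != "correlated"
                background.append(tr.classes[g])
        assert np.mean([c == "unclassified" for c in background]) >= 0.75

    def test_raising_tau_pos_never_adds_correlated_genes(self):
        cm, _ = block_correlation(seed=31)
        labels = cluster_correlation_profiles(cm, k=2, seed=0)
        low = classify_coherence(cm, labels, tau_pos=0.2)
        high = classify_coherence(cm, labels, tau_pos=0.6)
        low_set = {g for g, c in low.items() if c == "correlated"}
        high_set = {g for g, c in high.items() if c == "correlated"}
        assert high_set <= low_set

    def test_all_singletons_unclassified(self, caplog):
        vals = np.eye(3)
        cm = CorrelationMatrix(["a", "b", "c"], vals, "t")
        with caplog.at_level("WARNING"):
            classes = classify_coherence(cm, np.array([1, 2, 3]))
        assert set(classes.values()) == {"unclassified"}

    def test_invalid_thresholds_rejected(self):
        cm, _ = block_correlation(seed=1)
        labels = cluster_correlation_profiles(cm, k=2, seed=0)
        with pytest.raises(ValueError):
            classify_coherence(cm, labels, tau_pos=-0.5, tau_neg=0.5)


class TestCrossTissue:
    def _results(self, seed=37, n_tissues=3):
        panels, truth = simulate_tissue_panel(GENES, n_tissues=n_tissues,
                                              n_donors=150, r_within=0.9,
                                              seed=seed)
        results = {t: analyze_tissue(p, GENES, seed=1) for t, p in panels.items()}
        return results, truth

    def test_single_tissue_identity_order(self):
        results, _ = self._results(n_tissues=1)
        ordered = cross_tissue_order(results, "brain")
        ref = results["brain"]
        labels_in_order = [
            int(ref.labels[ref.matrix.gene_ids.index(g)]) for g in ordered.display_order
        ]
        assert labels_in_order == sorted(labels_in_order)
        assert set(ordered.display_order) == set(ref.matrix.gene_ids)

    def test_matrices_reindexed_to_reference_order(self):
        results, _ = self._results()
        ordered = cross_tissue_order(results, "brain")
        for tissue, mat in ordered.ordered_matrices.items():
            assert list(mat.index) == ordered.display_order
            assert list(mat.columns) == ordered.display_order
        assert set(ordered.assignment["tissue"]) == set(results)

    def test_cross_tissue_agreement_below_within_tissue_recovery(self):
        results, truth = self._results()
        tissues = list(results)
        # within-tissue: labels vs planted truth
        within = []
        for t in tissues:
            genes = results[t].matrix.gene_ids
            true = [truth.module_assignment[t][g] for g in genes]
            within.append(adjusted_rand_score(true, results[t].labels))
        # across tissues: labelings of two different tissues
        g0 = results[tissues[0]].matrix.gene_ids
        lab0 = results[tissues[0]].labels
        pos1 = {g: i for i, g in enumerate(results[tissues[1]].matrix.gene_ids)}
        lab1 = [results[tissues[1]].labels[pos1[g]] for g in g0]
        across = adjusted_rand_score(lab0, lab1)
        assert min(within) > 0.9
        assert across < min(within) - 0.3  # membership re-drawn per tissue

    def test_missing_reference_rejected(self):
        results, _ = self._results(n_tissues=2)
        with pytest.raises(ValueError, match="reference"):
            cross_tissue_order(results, "kidney")
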