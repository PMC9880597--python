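import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.base import clone

from thalseq import (
    GeneCellMatrix,
    LineageSpec,
    SimulationSpec,
    anchor_correlated_features,
    assign_cells,
    cluster_feature_genes,
    gate_binary_marker,
    normalize_cpt,
    simulate_lineage,
    suggest_group_labels,
    MarkerClassifier,
)
from tests.conftest import truth_gene_sets


def expr_matrix(X, genes=None, barcodes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"G{i}" for i in range(X.shape[0])]
    barcodes = barcodes or [f"B{i}" for i in range(X.shape[1])]
    return GeneCellMatrix(sp.csr_matrix(X), genes, barcodes)


def block_structured_expression(seed=0, n_cells=150, block=20, n_anchors=3):
    """Each anchor drives its own block of genes; blocks are independent."""
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_anchors, n_cells))
    rows, genes = [], []
    for a in range(n_anchors):
        genes.append(f"Anchor{a}")
        rows.append(factors[a])
        for g in range(block):
            genes.append(f"A{a}_g{g}")
            rows.append(factors[a] + 0.3 * rng.normal(size=n_cells))
    # unrelated noise genes
    for g in range(40):
        genes.append(f"Noise{g}")
        rows.append(rng.normal(size=n_cells))
    return expr_matrix(np.array(rows), genes)


class TestAnchorCorrelatedFeatures:
    def test_positives_lie_in_own_block_vs_bruteforce(self):
        expr = block_structured_expression()
        anchors = ("Anchor0", "Anchor1", "Anchor2")
        panel = anchor_correlated_features(expr, anchors, k=10)
        dense = np.asarray(expr.values.todense())
        corr = np.corrcoef(dense)
        for a, anchor in enumerate(anchors):
            ai = expr.gene_index(anchor)
            brute_top = set(
                np.array(expr.gene_symbols)[np.argsort(-corr[ai])[:10]]
            )
            selected = set(
                panel.correlations.query("anchor == @anchor and direction == 'pos'")["gene"]
            )
            assert selected == brute_top
            assert all(g.startswith(f"A{a}_") or g == anchor for g in selected)

    def test_anchor_is_its_own_top_positive(self):
        expr = block_structured_expression()
        panel = anchor_correlated_features(expr, ("Anchor0",), k=3)
        top = panel.correlations.query("direction == 'pos'").iloc[0]
        assert top["gene"] == "Anchor0"
        assert top["r"] == pytest.approx(1.0)

    def test_panel_size_bounded_by_2k_per_anchor(self, progenitor_logcpt):
        panel = anchor_correlated_features(
            progenitor_logcpt, ("Nkx2-2", "Olig2", "Dbx1", "Rspo3"), k=10
        )
        assert 0 < len(panel.panel_genes) <= 80

    def test_k_zero_gives_empty_panel(self, progenitor_logcpt):
        panel = anchor_correlated_features(progenitor_logcpt, ("Nkx2-2",), k=0)
        assert panel.panel_genes == []

    def test_invariant_to_cell_order(self):
        expr = block_structured_expression(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.n_cells)
        shuffled = GeneCellMatrix(
            expr.values[:, perm], expr.gene_symbols,
            [expr.barcodes[i] for i in perm],
        )
        p1 = anchor_correlated_features(expr, ("Anchor0", "Anchor1"), k=8)
        p2 = anchor_correlated_features(shuffled, ("Anchor0", "Anchor1"), k=8)
        assert p1.panel_genes == p2.panel_genes

    def test_missing_anchor_raises(self, progenitor_logcpt):
        with pytest.raises(KeyError, match="Nonesuch"):
            anchor_correlated_features(progenitor_logcpt, ("Nonesuch",), k=5)

    def test_constant_anchor_raises(self):
        expr = expr_matrix([[1, 1, 1], [0, 1, 2]])
        with pytest.raises(ValueError, match="variance"):
            anchor_correlated_features(expr, ("G0",), k=1)


class TestClusterFeatureGenes:
    def test_two_perfect_blocks_recovered(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([base, 2 * base, -base, 5 - base])
        expr = expr_matrix(X, ["P1", "P2", "N1", "N2"])
        panel = anchor_correlated_features(expr, ("P1",), k=2)
        panel.panel_genes = ["P1", "P2", "N1", "N2"]
        groups = cluster_feature_genes(expr, panel, 2)
        assert sorted(map(tuple, groups)) == [("N1", "N2"), ("P1", "P2")]

    def test_three_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        factors = rng.normal(size=(3, 200))
        rows, genes = [], []
        for b in range(3):
            for g in range(6):
                genes.append(f"B{b}_g{g}")
                rows.append(factors[b] + 0.35 * rng.normal(size=200))
        expr = expr_matrix(np.array(rows), genes)
        panel = anchor_correlated_features(expr, (genes[0],), k=1)
        panel.panel_genes = genes
        groups = cluster_feature_genes(expr, panel, 3)
        blocks = [sorted(g for g in genes if g.startswith(f"B{b}_")) for b in range(3)]
        assert sorted(map(tuple, groups)) == sorted(map(tuple, blocks))

    def test_singletons_at_full_cut(self):
        expr = block_structured_expression(seed=1)
        panel = anchor_correlated_features(expr, ("Anchor0",), k=3)
        groups = cluster_feature_genes(expr, panel, len(panel.panel_genes))
        assert all(len(g) == 1 for g in groups)

    def test_constant_gene_dropped_with_warning(self, caplog):
        X = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]])
        expr = expr_matrix(X, ["Ga", "Gb", "Const"])
        panel = anchor_correlated_features(expr, ("Ga",), k=1)
        panel.panel_genes = ["Ga", "Gb", "Const"]
        with caplog.at_level("WARNING"):
            groups = cluster_feature_genes(expr, panel, 2)
        assert all("Const" not in g for g in groups)


class TestAssignCells:
    def test_exclusive_expression_assigned_cleanly(self):
        expr = expr_matrix([[10, 0], [0, 10]], ["a1", "b1"])
        out = assign_cells(expr, {"A": ["a1"], "B": ["b1"]}, subpop_order=("A", "B"))
        assert out["label"].tolist() == ["A", "B"]
        assert not out["tie"].any()

    def test_tie_goes_to_most_rostral_and_is_flagged(self):
        expr = expr_matrix([[5], [5]], ["a1", "b1"])
        out = assign_cells(expr, {"B": ["b1"], "A": ["a1"]}, subpop_order=("A", "B"))
        assert out["label"].tolist() == ["A"]
        assert out["tie"].tolist() == [True]

    def test_all_zero_cell_unassigned(self):
        expr = expr_matrix([[0], [0]], ["a1", "b1"])
        out = assign_cells(expr, {"A": ["a1"], "B": ["b1"]})
        assert out["label"].tolist() == ["unassigned"]

    def test_size_normalization_removes_large_set_bias(self):
        # set B has 4 genes each at 3; set A one gene at 5: A wins normalized
        expr = expr_matrix([[5], [3], [3], [3], [3]], ["a1", "b1", "b2", "b3", "b4"])
        out = assign_cells(expr, {"A": ["a1"], "B": ["b1", "b2", "b3", "b4"]})
        assert out["label"].tolist() == ["A"]
        raw = assign_cells(expr, {"A": ["a1"], "B": ["b1", "b2", "b3", "b4"]},
                           size_normalize=False)
        assert raw["label"].tolist() == ["B"]

    def test_labels_invariant_to_library_size(self, progenitor_dataset, config):
        counts = progenitor_dataset.counts
        cpt = normalize_cpt(counts, config)
        sets = truth_gene_sets()
        base = assign_cells(cpt, sets)["label"]
        scaled_counts = counts.values.copy() * 7
        scaled = GeneCellMatrix(scaled_counts.astype(float), counts.gene_symbols,
                                counts.barcodes)
        sums = np.asarray(scaled.values.sum(axis=0)).ravel()
        scaled_cpt = GeneCellMatrix(
            scaled.values.multiply(1000.0 / sums).tocsr(),
            counts.gene_symbols, counts.barcodes,
        )
        again = assign_cells(scaled_cpt, sets)["label"]
        assert (base == again).all()

    def test_hard_boundary_accuracy(self, progenitor_dataset, config):
        cpt = normalize_cpt(progenitor_dataset.counts, config)
        out = assign_cells(cpt, truth_gene_sets())
        acc = (out["label"].to_numpy() == progenitor_dataset.truth["domain"].to_numpy()).mean()
        assert acc >= 0.95

    def test_empty_gene_set_rejected(self):
        expr = expr_matrix([[1]], ["a1"])
        with pytest.raises(ValueError):
            assign_cells(expr, {"A": []})


class TestGateBinaryMarker:
    def test_default_threshold_is_count_one(self):
        expr = expr_matrix([[0, 1, 3]], ["Sox2"])
        assert gate_binary_marker(expr, "Sox2").tolist() == [False, True, True]

    def test_cpt_threshold_mode(self):
        expr = expr_matrix([[0.5, 2.0]], ["Sox2"])
        assert gate_binary_marker(expr, "Sox2", threshold=1.0).tolist() == [False, True]

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            gate_binary_marker(expr_matrix([[1]], ["Ga"]), "Sox2")

    def test_lineage_double_positive_rare_late(self):
        ds = simulate_lineage(SimulationSpec(rng_seed=0, n_cells_control=1000))
        late = ds.truth["pseudotime"].to_numpy() > 0.5
        pos_a = gate_binary_marker(ds.counts, "Sox2")
        pos_b = gate_binary_marker(ds.counts, "Foxp2")
        double = (pos_a & pos_b)[late].mean()
        assert double < 0.05


class TestMarkerClassifier:
    def test_fit_predict_recovers_anchored_domains(self, progenitor_dataset,
                                                   progenitor_logcpt, config):
        clf = MarkerClassifier(anchors=("Nkx2-2", "Olig2", "Dbx1", "Rspo3", "Pax6"),
                               k=6).fit(progenitor_logcpt)
        cpt = normalize_cpt(progenitor_dataset.counts, config)
        pred = clf.predict(cpt)
        truth = progenitor_dataset.truth["domain"].to_numpy()
        anchor_of = {"rTh.Pro": "Nkx2-2", "cTh.Pro1": "Olig2", "cTh.Pro2": "Dbx1",
                     "epiTh.Pro": "Rspo3", "preT.Pro": "Pax6"}
        acc = np.mean([p == anchor_of[t] for p, t in zip(pred, truth)])
        assert acc >= 0.95

    def test_explicit_gene_sets_bypass_derivation(self, progenitor_dataset, config):
        clf = MarkerClassifier(gene_sets=truth_gene_sets())
        cpt = normalize_cpt(progenitor_dataset.counts, config)
        clf.fit(cpt)
        acc = clf.score(cpt, progenitor_dataset.truth["domain"].to_numpy())
        assert acc >= 0.95

    def test_sklearn_params_round_trip(self):
        clf = MarkerClassifier(k=4)
        cloned = clone(clf)
        assert cloned.get_params()["k"] == 4

    def test_suggested_labels_name_groups_by_anchor(self, progenitor_logcpt):
        panel = anchor_correlated_features(
            progenitor_logcpt, ("Nkx2-2", "Olig2", "Dbx1", "Rspo3"), k=8
        )
        groups = cluster_feature_genes(progenitor_logcpt, panel, 4)
        labels = suggest_group_labels(groups, panel)
        assert set(labels) == {"Nkx2-2", "Olig2", "Dbx1", "Rspo3"}
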