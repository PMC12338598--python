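"""Phase scoring, ANOVA R^2, and the phase-variance gene filter."""

import numpy as np
import pytest

from sepalcoord.cell_cycle import (assign_phase, log_normalize, module_score,
                                   remove_cc_genes, score_phases,
                                   variance_explained,
                                   variance_explained_all)
from sepalcoord.synthetic import ScSimConfig, simulate_sc
from conftest import make_matrix


class TestModuleScore:
    def test_constant_expression_scores_zero(self):
        expr = np.full((30, 8), 2.5)
        genes = [f"G{i}" for i in range(30)]
        score = module_score(expr, genes, genes[:5], n_bins=3, n_ctrl=5, seed=0)
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_additive_shift_in_one_cell_equals_delta(self):
        rng = np.random.default_rng(0)
        n_genes, n_cells = 30, 10
        base = rng.normal(size=n_genes)
        expr = np.tile(base[:, None], (1, n_cells))
        targets = [f"G{i}" for i in range(0, 30, 6)]
        delta = 0.7
        for g in range(0, 30, 6):
            expr[g, 3] += delta
        genes = [f"G{i}" for i in range(n_genes)]
        score = module_score(expr, genes, targets, n_bins=3, n_ctrl=5, seed=1)
        # cell 3 carries the shift; in all other cells target and control
        # genes agree bin-by-bin only in expectation, so compare cell 3 to
        # the other cells rather than to 0
        others = np.delete(score, 3)
        assert score[3] - others.mean() == pytest.approx(delta, abs=1e-9)

    def test_closed_form_when_controls_are_degenerate(self):
        # every non-target gene in a bin has the same per-cell expression,
        # so the control mean is independent of the random draw and the
        # score is computable by hand
        n_cells = 6
        rng = np.random.default_rng(2)
        cell_effect = rng.normal(size=n_cells)
        n_genes = 30
        expr = np.zeros((n_genes, n_cells))
        genes = [f"G{i}" for i in range(n_genes)]
        # 3 bins of 10 genes by mean level: bins at levels 0, 5, 10
        levels = np.repeat([0.0, 5.0, 10.0], 10)
        expr[:] = levels[:, None] + cell_effect[None, :]
        targets = ["G0", "G10", "G20"]          # one target per bin
        expr[[0, 10, 20], :] += 1.5              # targets sit above their bins
        score = module_score(expr, genes, targets, n_bins=3, n_ctrl=4, seed=3)
        # target mean = (levels + 1.5) mean; control mean = levels mean
        np.testing.assert_allclose(score, 1.5, atol=1e-9)

    def test_invariant_under_global_constant(self):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=(40, 12))
        genes = [f"G{i}" for i in range(40)]
        targets = genes[::7]
        a = module_score(expr, genes, targets, n_bins=4, n_ctrl=6, seed=5)
        b = module_score(expr + 3.2, genes, targets, n_bins=4, n_ctrl=6, seed=5)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_unresolvable_target_set_errors(self):
        expr = np.zeros((5, 3))
        with pytest.raises(ValueError, match="zero genes"):
            module_score(expr, [f"G{i}" for i in range(5)], ["NOPE"], seed=0)


@pytest.mark.parametrize(
    "s,g2m,expected",
    [
        (-0.1, -0.2, "G1"),
        (0.5, 0.2, "S"),
        (0.2, 0.5, "G2M"),
        (0.0, 0.0, "G1"),
        (0.3, 0.3, "S"),       # positive tie goes to S
        (-0.5, 0.1, "G2M"),
    ],
)
def test_assign_phase(s, g2m, expected):
    assert assign_phase(s, g2m) == expected


class TestVarianceExplained:
    def test_identical_group_means_give_zero(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        labels = np.array(["G1", "G1", "S", "S"])
        assert variance_explained(values, labels) == pytest.approx(0.0)

    def test_constant_within_groups_gives_one(self):
        values = np.array([1.0, 1.0, 5.0, 5.0, 9.0, 9.0])
        labels = np.array(["G1", "G1", "S", "S", "G2M", "G2M"])
        assert variance_explained(values, labels) == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # groups (1,2), (3,4), (5,6): SS_between = 16, SS_total = 17.5
        values = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        labels = np.array(["G1", "G1", "S", "S", "G2M", "G2M"])
        assert variance_explained(values, labels) == pytest.approx(16 / 17.5)

    def test_single_phase_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            variance_explained(np.arange(4.0), np.array(["S"] * 4))

    def test_matches_bruteforce_oracle(self, anova_oracle):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 50)
            labels = rng.choice(["G1", "S", "G2M"], size=n)
            if len(np.unique(labels)) < 2:
                continue
            values = rng.normal(size=n)
            assert variance_explained(values, labels) == pytest.approx(
                anova_oracle(values, labels), abs=1e-10)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 15))
        labels = rng.choice(["G1", "S", "G2M"], size=15)
        all_r2 = variance_explained_all(X, labels)
        for g in range(20):
            assert all_r2[g] == pytest.approx(
                variance_explained(X[g], labels), abs=1e-12)


class TestRemoveCcGenes:
    def test_threshold_one_removes_nothing(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.poisson(5.0, size=(20, 12)) + 1)
        labels = rng.choice(["G1", "S"], size=12)
        reduced, report = remove_cc_genes(m, labels, threshold=1.0)
        assert reduced.n_genes == 20
        assert not report["removed"].any()

    def test_exact_threshold_value_retained(self):
        # the rule is strictly-greater-than: R^2 == threshold stays
        rng = np.random.default_rng(10)
        m = make_matrix(rng.poisson(5.0, size=(10, 30)) + 1)
        labels = np.array(["G1", "S", "G2M"] * 10)
        from sepalcoord.cell_cycle import log_normalize, variance_explained_all
        r2 = variance_explained_all(log_normalize(m), labels)
        _, report = remove_cc_genes(m, labels, threshold=float(r2.max()))
        assert not report["removed"].any()

    def test_mito_genes_always_removed(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.poisson(5.0, size=(10, 12)) + 1,
                        mito=[True, True] + [False] * 8)
        labels = rng.choice(["G1", "S"], size=12)
        reduced, report = remove_cc_genes(m, labels, threshold=1.0)
        assert reduced.n_genes == 8
        assert set(report.loc[report["removed"], "reason"]) == {"mitochondrial"}

    def test_planted_phase_genes_recovered(self):
        cfg = ScSimConfig(n_genes=200, n_cells_per_cluster=80, n_clusters=2,
                          phase_gene_counts={"S": 10, "G2M": 10},
                          phase_effect=3.0, n_mito_genes=1, n_chloro_genes=1,
                          seed=12)
        matrix, truth = simulate_sc(cfg)
        labels = truth.cells["phase_truth"].to_numpy()
        _, report = remove_cc_genes(matrix, labels, threshold=0.03)
        planted = set(matrix.gene_ids[np.concatenate(
            [truth.universe.phase_idx["S"], truth.universe.phase_idx["G2M"]])])
        removed_cc = set(report.loc[report["reason"] == "cell_cycle", "gene_id"])
        assert len(planted & removed_cc) >= 18

    def test_never_removes_below_threshold_unless_mito(self):
        rng = np.random.default_rng(13)
        m = make_matrix(rng.poisson(3.0, size=(30, 24)) + 1,
                        mito=[True] * 3 + [False] * 27)
        labels = np.array(["G1", "S", "G2M"] * 8)
        r2 = variance_explained_all(log_normalize(m), labels)
        _, report = remove_cc_genes(m, labels, threshold=0.2)
        mito = m.gene_flags["mito"].to_numpy()
        bad = report["removed"] & ~mito & (r2 <= 0.2)
        assert not bad.any()


def test_score_phases_recovers_truth_majority():
    cfg = ScSimConfig(n_genes=300, n_cells_per_cluster=60, n_clusters=2,
                      phase_effect=4.0, seed=14)
    matrix, truth = simulate_sc(cfg)
    s_genes, g2m_genes = truth.universe.cc_gene_lists()
    phases = score_phases(matrix, s_genes, g2m_genes, seed=0)
    agree = (phases.phases.to_numpy() == truth.cells["phase_truth"].to_numpy()).mean()
    assert agree > 0.7
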