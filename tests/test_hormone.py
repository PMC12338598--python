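"""Wilcoxon rank-sum, cluster contrasts, stars, and direction inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sepalcoord.hormone import (bonferroni_threshold, contrast_clusters,
                                direction_calls, dot_size, infer_direction,
                                score_cells, star_annotation,
                                wilcoxon_rank_sum)
from sepalcoord.qc import set_fractions
from sepalcoord.synthetic import (HormoneSetSpec, ScSimConfig, simulate_sc)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_complete_separation_3v3(self):
        # 2 of the C(6,3)=20 equally likely rank splits are this extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_complete_separation_4v4(self):
        assert wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    def test_symmetric_in_sample_order(self):
        x, y = [1.0, 3.0, 5.5], [2.0, 4.0, 9.0, 10.0]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_agrees_with_enumeration_small_samples(self, wilcoxon_oracle):
        # exhaustive over all tie-free rank patterns for a grid of sizes
        for nx, ny in [(1, 3), (2, 2), (2, 4), (3, 3), (4, 4), (2, 6)]:
            n = nx + ny
            values = np.arange(1.0, n + 1)
            for xs in itertools.combinations(range(n), nx):
                x = values[list(xs)]
                y = np.delete(values, list(xs))
                assert wilcoxon_rank_sum(x, y) == pytest.approx(
                    wilcoxon_oracle(x, y), abs=1e-12), (x, y)


class TestBonferroni:
    def test_dotplot_family_threshold(self):
        # 17 clusters x 12 hormone sets at alpha 0.05
        assert bonferroni_threshold(0.05, 17 * 12) == pytest.approx(0.000245, abs=5e-7)

    def test_star_thresholds_17_clusters(self):
        assert 0.05 / 17 == pytest.approx(0.00294, abs=5e-6)
        assert 0.01 / 17 == pytest.approx(0.00059, abs=5e-6)
        assert star_annotation(0.0028, 17) == 1
        assert star_annotation(0.0005, 17) == 2
        assert star_annotation(5e-5, 17) == 3
        assert star_annotation(1e-7, 17) == 4

    def test_no_stars_for_large_p(self):
        assert star_annotation(0.5, 17) == 0

    def test_dot_size_monotone_in_p(self):
        ps = [1.0, 0.5, 0.01, 1e-6]
        sizes = [dot_size(p) for p in ps]
        assert sizes == sorted(sizes)
        assert sizes[0] == 0.0


def _label_frame(scores, clusters, genotypes):
    return contrast_clusters(scores, clusters, genotypes, alpha=0.05,
                             reference="WT", mutant="drmy1")


class TestContrastClusters:
    def _null_scores(self, seed=0, n=30, n_clusters=2):
        rng = np.random.default_rng(seed)
        cells = n * n_clusters * 2
        idx = [f"c{i}" for i in range(cells)]
        scores = pd.DataFrame({"auxin_up": rng.normal(5, 1, cells),
                               "auxin_down": rng.normal(5, 1, cells)}, index=idx)
        clusters = np.repeat(np.arange(n_clusters), n * 2)
        genotypes = np.tile(["WT"] * n + ["drmy1"] * n, n_clusters)
        return scores, clusters, genotypes

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(5, 1, 40)
        scores = pd.DataFrame({"auxin_up": np.tile(vals, 2)},
                              index=[f"c{i}" for i in range(80)])
        clusters = np.zeros(80, dtype=int)
        genotypes = ["WT"] * 40 + ["drmy1"] * 40
        table = _label_frame(scores, clusters, genotypes)
        row = table.iloc[0]
        assert row["diff"] == pytest.approx(0.0)
        assert not row["significant"]
        assert row["p"] == pytest.approx(1.0, abs=0.05)

    def test_diff_is_mutant_minus_reference(self):
        scores = pd.DataFrame({"auxin_up": [1.0, 2.0, 5.0, 6.0]},
                              index=list("abcd"))
        table = _label_frame(scores, [0] * 4, ["WT", "WT", "drmy1", "drmy1"])
        assert table.iloc[0]["diff"] == pytest.approx(4.0)
        assert table.iloc[0]["mean_ref"] == pytest.approx(1.5)
        assert table.iloc[0]["mean_mut"] == pytest.approx(5.5)

    def test_family_derived_from_inputs(self):
        scores, clusters, genotypes = self._null_scores(n_clusters=3)
        table = _label_frame(scores, clusters, genotypes)
        assert table.attrs["n_tests"] == 3 * 2
        assert table.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 6)
        assert len(table) == 6

    def test_significance_invariant_to_cluster_relabeling(self):
        scores, clusters, genotypes = self._null_scores(seed=3, n_clusters=3)
        table = _label_frame(scores, clusters, genotypes)
        relabel = {0: "zeta", 1: "alpha", 2: "mid"}
        renamed = [relabel[c] for c in clusters]
        table2 = _label_frame(scores, renamed, genotypes)
        merged = table.assign(cluster=[relabel[c] for c in table["cluster"]]).merge(
            table2, on=["cluster", "hormone", "direction"], suffixes=("_a", "_b"))
        assert (merged["significant_a"] == merged["significant_b"]).all()
        np.testing.assert_allclose(merged["p_a"], merged["p_b"])

    def test_small_cluster_emits_p_one_with_warning(self, caplog):
        scores = pd.DataFrame({"auxin_up": [1.0, 2.0, 3.0]}, index=list("abc"))
        with caplog.at_level("WARNING", logger="sepalcoord"):
            table = _label_frame(scores, [0, 0, 0], ["WT", "WT", "drmy1"])
        assert table.iloc[0]["p"] == 1.0
        assert "<2 cells" in caplog.text

    def test_requires_two_genotypes(self):
        scores = pd.DataFrame({"auxin_up": [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match="two genotype"):
            contrast_clusters(scores, [0, 0], ["WT", "WT"])


class TestScoreCells:
    def test_single_set_reduces_to_fraction(self, tiny_matrix, two_set_collection):
        table = score_cells(tiny_matrix, two_set_collection)
        np.testing.assert_allclose(
            table["brassinosteroid_up"].to_numpy(),
            set_fractions(tiny_matrix, ["G1"]))

    def test_disjoint_covering_sets_sum_to_100(self, tiny_matrix):
        from sepalcoord.io import GeneSet, GeneSetCollection
        coll = GeneSetCollection([
            GeneSet("x", "up", ("G0", "G1")),
            GeneSet("x", "down", ("G2", "G3")),
        ])
        table = score_cells(tiny_matrix, coll)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)

    def test_planted_effect_lowers_mutant_down_set(self):
        cfg = ScSimConfig(
            n_genes=400, n_cells_per_cluster=150, n_clusters=2,
            hormone_sets={"brassinosteroid": HormoneSetSpec(25, 25, beta=0.3)},
            latent_mean={"WT": [0.0, 0.0], "drmy1": [0.0, 1.5]},
            seed=5)
        matrix, truth = simulate_sc(cfg)
        frac = score_cells(matrix, truth.universe.gene_sets())
        meta = matrix.cell_meta
        in_cl = (meta["cluster"] == 1).to_numpy()
        mut = (meta["genotype"] == "drmy1").to_numpy()
        down = frac["brassinosteroid_down"].to_numpy()
        assert down[in_cl & mut].mean() < down[in_cl & ~mut].mean()


class TestInferDirection:
    def _row(self, direction, diff, significant, cluster=1, hormone="brassinosteroid"):
        return {"cluster": cluster, "hormone": hormone, "direction": direction,
                "diff": diff, "significant": significant}

    def test_concordant_evidence_is_strong(self):
        call, conf = infer_direction(self._row("up", 2.0, True),
                                     self._row("down", -1.0, True))
        assert (call, conf) == ("higher_in_mutant", "strong")

    def test_single_down_set_evidence_is_weak(self):
        # lower down-set expression in the mutant alone suggests higher
        # signaling, weakly
        call, conf = infer_direction(self._row("up", 0.3, False),
                                     self._row("down", -1.0, True))
        assert (call, conf) == ("higher_in_mutant", "weak")

    def test_no_evidence_is_inconclusive(self):
        call, conf = infer_direction(self._row("up", 0.5, False),
                                     self._row("down", 0.2, False))
        assert call == "inconclusive" and conf is None

    def test_conflicting_evidence_is_inconclusive(self):
        call, _ = infer_direction(self._row("up", 2.0, True),
                                  self._row("down", 1.0, True))
        assert call == "inconclusive"

    def test_mismatched_rows_error(self):
        with pytest.raises(ValueError, match="different"):
            infer_direction(self._row("up", 1.0, True, cluster=1),
                            self._row("down", -1.0, True, cluster=2))

    def test_direction_calls_table(self):
        table = pd.DataFrame([
            self._row("up", 2.0, True) | {"p": 1e-9},
            self._row("down", -1.0, True) | {"p": 1e-9},
        ])
        calls = direction_calls(table)
        assert calls.iloc[0]["call"] == "higher_in_mutant"
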