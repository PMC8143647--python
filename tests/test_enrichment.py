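"""Gland-enrichment calling: filtering, z-scores, clustering, selection."""

import numpy as np
import pandas as pd
import pytest

import glandscreen as gs
from glandscreen.enrichment import ZeroVarianceError, pca_fg_loadings


class TestFilterValid:
    def test_fg_plus_one_other_removed(self, tiny_matrix):
        assert "p2" not in gs.filter_valid(tiny_matrix).data.index

    def test_fg_plus_two_tissues_retained(self, tiny_matrix):
        assert "p1" in gs.filter_valid(tiny_matrix).data.index

    def test_no_fg_value_removed(self, tiny_matrix):
        assert "p3" not in gs.filter_valid(tiny_matrix).data.index

    def test_serum_dropped_and_not_counted(self, tiny_matrix):
        filtered = gs.filter_valid(tiny_matrix)
        assert "serum" not in filtered.data.columns
        # p1's serum value must not have counted toward the two "other" values
        assert filtered.data.loc["p1"].notna().sum() == 3

    def test_idempotent(self, tiny_matrix):
        once = gs.filter_valid(tiny_matrix)
        twice = gs.filter_valid(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestZscore:
    def test_log_decade_row(self):
        m = gs.IntensityMatrix(
            data=pd.DataFrame({"FG": [10.0], "a": [100.0], "b": [1000.0]},
                              index=["p"]),
            roles={"FG": "FG", "a": "tissue", "b": "tissue"},
        )
        z = gs.zscore_transform(m)
        assert np.allclose(z.data.loc["p"].to_numpy(),
                           [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_row_is_error_naming_protein(self):
        m = gs.IntensityMatrix(
            data=pd.DataFrame({"FG": [7.0], "a": [7.0], "b": [7.0]},
                              index=["flatling"]),
            roles={"FG": "FG", "a": "tissue", "b": "tissue"},
        )
        with pytest.raises(ZeroVarianceError, match="flatling"):
            gs.zscore_transform(m)

    def test_missing_imputed_below_row_minimum(self):
        m = gs.IntensityMatrix(
            data=pd.DataFrame({"FG": [10.0], "a": [100.0], "b": [1000.0],
                               "c": [np.nan]}, index=["p"]),
            roles={"FG": "FG", "a": "tissue", "b": "tissue", "c": "tissue"},
        )
        z = gs.zscore_transform(m, downshift=0.5)
        row = z.data.loc["p"]
        assert row["c"] == pytest.approx(row["FG"] - 0.5)


class TestClustering:
    def _two_group_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        hi = rng.normal(3.0, 0.2, size=(20, 4))
        lo = rng.normal(-1.0, 0.2, size=(30, 4))
        data = pd.DataFrame(np.vstack([hi, lo]),
                            index=[f"p{i}" for i in range(50)],
                            columns=["FG", "SF", "a", "b"])
        roles = {"FG": "FG", "SF": "SF", "a": "tissue", "b": "tissue"}
        return gs.IntensityMatrix(data=data, roles=roles)

    def test_two_planted_groups_recovered_at_k2(self):
        m = self._two_group_matrix()
        labels, fg = gs.cluster_proteins(m, k=2, seed=0)
        hi_labels = {labels[f"p{i}"] for i in range(20)}
        lo_labels = {labels[f"p{i}"] for i in range(20, 50)}
        assert len(hi_labels) == 1 and len(lo_labels) == 1
        assert hi_labels != lo_labels
        assert fg == hi_labels.pop()  # FG-high group is the FG cluster

    def test_k1_trivially_fg_cluster(self):
        m = self._two_group_matrix()
        labels, fg = gs.cluster_proteins(m, k=1, seed=0)
        assert set(labels.values()) == {0} and fg == 0

    def test_same_seed_identical_labels(self):
        m = self._two_group_matrix()
        assert gs.cluster_proteins(m, k=3, seed=7) == \
               gs.cluster_proteins(m, k=3, seed=7)


class TestSelectEnriched:
    def _setup(self):
        m = TestClustering()._two_group_matrix()
        labels, fg = gs.cluster_proteins(m, k=2, seed=0)
        return m, labels, fg

    def test_quantile_zero_selects_whole_cluster(self):
        m, labels, fg = self._setup()
        sel, _ = gs.select_enriched(m, labels, fg, loading_quantile=0.0)
        assert sel == {p for p, l in labels.items() if l == fg}

    def test_quantile_one_selects_at_most_one(self):
        m, labels, fg = self._setup()
        sel, _ = gs.select_enriched(m, labels, fg, loading_quantile=1.0)
        assert len(sel) <= 1

    def test_loading_orientation_puts_fg_high_positive(self):
        m, labels, fg = self._setup()
        loadings = pca_fg_loadings(m)
        hi = np.mean([loadings[f"p{i}"] for i in range(20)])
        lo = np.mean([loadings[f"p{i}"] for i in range(20, 50)])
        assert hi > lo


class TestUniqueToFg:
    def test_fg_only_protein_included(self, tiny_matrix):
        assert "p4" in gs.unique_to_fg(tiny_matrix)

    def test_fg_plus_tissue_excluded(self, tiny_matrix):
        assert gs.unique_to_fg(tiny_matrix) == {"p4"}

    def test_empty_matrix_gives_empty_set(self):
        m = gs.IntensityMatrix(
            data=pd.DataFrame(columns=["FG", "a"], dtype=float),
            roles={"FG": "FG", "a": "tissue"},
        )
        assert gs.unique_to_fg(m) == frozenset()


class TestCombineAndRank:
    def test_disjoint_sets_sum(self, tiny_matrix):
        unique = frozenset(f"u{i}" for i in range(337))
        enriched = frozenset(f"e{i}" for i in range(428))
        res = gs.combine_and_rank(unique, enriched, tiny_matrix)
        assert len(res.combined_set) == 765

    def test_overlap_counted_once(self, tiny_matrix):
        res = gs.combine_and_rank(frozenset("ab"), frozenset("bc"),
                                  tiny_matrix)
        assert res.combined_set == frozenset("abc")

    def test_cardinality_identity(self, tiny_matrix):
        u, e = frozenset("abcd"), frozenset("cdef")
        res = gs.combine_and_rank(u, e, tiny_matrix)
        assert len(res.combined_set) == len(u) + len(e) - len(u & e)

    def test_ranking_by_fg_intensity_descending(self):
        data = pd.DataFrame({"FG": [5.0, 50.0, 0.5], "a": [1, 1, 1]},
                            index=["mid", "top", "low"], dtype=float)
        m = gs.IntensityMatrix(data=data, roles={"FG": "FG", "a": "tissue"})
        res = gs.combine_and_rank(frozenset(), frozenset(data.index), m)
        assert res.ranking == ("top", "mid", "low")


class TestFractionAbundance:
    def test_share_arithmetic(self):
        data = pd.DataFrame({"FG_f1": [20.0, 30.0, 50.0]},
                            index=["a", "b", "c"])
        m = gs.IntensityMatrix(data=data, roles={"FG_f1": "FG"})
        table = gs.fraction_abundance(m, top_n=3)
        share_a = table[table.protein_id == "a"].share_percent.iloc[0]
        assert share_a == pytest.approx(20.0)

    def test_single_protein_fraction_is_100(self):
        data = pd.DataFrame({"FG_f1": [42.0]}, index=["solo"])
        m = gs.IntensityMatrix(data=data, roles={"FG_f1": "FG"})
        assert gs.fraction_abundance(m).share_percent.iloc[0] == 100.0

    def test_shares_sum_to_100(self):
        spec = gs.SimulationSpec(n_proteins=30, mean_length=40, sd_length=5,
                                 planted_enriched=3, missing_rate=0.0, seed=2)
        m, _ = gs.simulate_intensity_matrix(spec, gs.simulate_proteome(spec))
        table = gs.fraction_abundance(m, top_n=10_000)
        sums = table.groupby("sample").share_percent.sum()
        assert np.allclose(sums, 100.0)


class TestRecovery:
    def test_planted_enrichment_recovered_at_strong_fold(self):
        spec = gs.SimulationSpec(n_proteins=200, mean_length=40, sd_length=5,
                                 planted_enriched=20, enrichment_fold=100,
                                 missing_rate=0.1, seed=7)
        proteome = gs.simulate_proteome(spec)
        matrix, truth = gs.simulate_intensity_matrix(spec, proteome)
        res = gs.call_enrichment(matrix, k=6, loading_quantile=0.75, seed=7)
        inter = truth & res.enriched_set
        union = truth | res.enriched_set
        assert len(inter) / len(union) >= 0.9
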