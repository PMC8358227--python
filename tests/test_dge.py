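from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import hybridome as h
from hybridome.simulate import build_design, simulate_counts

from conftest import make_counts, make_sheet


def exact_ranksum_p(x, y):
    """Independent exact two-sided rank-sum p by full enumeration of all
    C(n+m, n) assignments of the pooled ranks to the first sample."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    n, total = len(x), len(pooled)
    mean = n * (total + 1) / 2
    sums = [sum(c) for c in combinations(range(1, total + 1), n)]
    extreme = sum(abs(s - mean) >= abs(obs - mean) for s in sums)
    return extreme / len(sums)


class TestSizeFactors:
    def test_hand_computed_example(self):
        # geometric means 141.42, 424.26; per-library ratio medians
        counts = make_counts([[100, 200], [300, 600]])
        sf = h.size_factors(counts)
        assert sf.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_libraries_get_equal_factors(self):
        counts = make_counts([[5, 5, 5], [80, 80, 80], [13, 13, 13]])
        sf = h.size_factors(counts)
        assert np.allclose(sf, sf.iloc[0])

    def test_single_library_convention(self):
        assert h.size_factors(make_counts([[7], [9]])).iloc[0] == 1.0

    def test_no_all_positive_feature_errors(self):
        with pytest.raises(ValueError, match="pseudocount|filter"):
            h.size_factors(make_counts([[0, 5], [3, 0]]))


class TestCpm:
    def test_column_sums_are_one_million(self, study):
        table = h.cpm(study.counts_genes)
        assert np.allclose(table.sum(axis=0), 1e6)

    def test_scale_invariance_of_one_library(self):
        counts = make_counts([[10, 20], [90, 30]])
        doubled = make_counts([[20, 20], [180, 30]])
        assert np.allclose(h.cpm(counts)["lib0"], h.cpm(doubled)["lib0"])

    def test_zero_column_errors(self):
        with pytest.raises(ValueError, match="zero column"):
            h.cpm(make_counts([[0, 1], [0, 2]]))


class TestStructuralFilter:
    def test_structural_classes_removed(self):
        clusters = [
            h.SrnaCluster("chr1", i * 100, i * 100 + 50, f"c{i}", "24", rc)
            for i, rc in enumerate(
                ["clean", "tRNA", "rRNA", "miRNA_annotated", "snoRNA", "clean"]
            )
        ]
        counts = make_counts(np.arange(12).reshape(6, 2),
                             feature_ids=[f"c{i}" for i in range(6)])
        kept, kept_counts = h.filter_srna_classes(clusters, counts)
        assert [c.cluster_id for c in kept] == ["c0", "c3", "c5"]
        assert kept_counts.feature_ids == ["c0", "c3", "c5"]

    def test_all_clean_is_identity(self, study):
        clean = [c for c in study.clusters if c.rna_class == "clean"]
        counts = study.counts_srna.subset_features([c.cluster_id for c in clean])
        kept, kept_counts = h.filter_srna_classes(clean, counts)
        assert kept == clean
        assert kept_counts.df.equals(counts.df)

    def test_id_mismatch_errors(self, study):
        with pytest.raises(ValueError, match="match"):
            h.filter_srna_classes(study.clusters[:-1], study.counts_srna)


class TestNbWaldTest:
    def test_identical_crosses_not_de(self, design):
        sheet, _ = design
        rng = np.random.default_rng(0)
        block = rng.poisson(200, size=(50, 3))
        counts = make_counts(np.tile(block, (1, 4)),
                             library_ids=sheet.library_ids)
        res = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        assert np.allclose(res["log2fc"], 0.0)
        assert not res["is_de"].any()

    def test_planted_effect_recovered(self, design):
        """A feature planted at hybrid-vs-normal log2FC = +4 is called DE
        over; the truth table is the oracle."""
        sheet, _ = design
        cfg = h.SimConfig(frac_de_genes=0.1, de_log2fc_magnitude=4.0,
                          dispersion=0.05, mode_proportions={"conserved": 1.0},
                          seed=21)
        counts, truth = simulate_counts(cfg, sheet, "genes",
                                        [f"f{i}" for i in range(500)])
        res = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        planted_up = truth.index[(truth["true_de"]) & (truth["true_log2fc"] > 0)]
        assert len(planted_up) > 5
        called = res.loc[planted_up]
        assert (called["direction"] == "over").mean() > 0.9
        assert called["log2fc"].mean() == pytest.approx(4.0, abs=0.5)

    def test_all_zero_feature_reported_untested(self, design):
        sheet, _ = design
        arr = np.vstack([np.zeros(12, dtype=int), np.full(12, 50)])
        counts = make_counts(arr, library_ids=sheet.library_ids)
        res = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        assert not res.loc["f0", "tested"]
        assert res.loc["f0", "p_raw"] == 1.0
        assert res.loc["f0", "log2fc"] == 0.0

    def test_scale_invariance_of_log2fc(self, design):
        """Multiplying one library's counts by a constant is absorbed by the
        size factors and leaves every log2FC unchanged (1e-6)."""
        sheet, _ = design
        cfg = h.SimConfig(frac_de_genes=0.1, mode_proportions={"conserved": 1.0},
                          seed=3)
        counts, _ = simulate_counts(cfg, sheet, "genes",
                                    [f"f{i}" for i in range(300)])
        res1 = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        scaled = counts.df.copy()
        scaled.iloc[:, 0] *= 7
        res2 = h.nb_wald_test(h.CountTable(scaled), sheet, h.GENE_PARAMS)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=1e-6)

    def test_de_partition_bookkeeping(self, design):
        sheet, _ = design
        cfg = h.SimConfig(frac_de_genes=0.2, seed=9)
        counts, _ = simulate_counts(cfg, sheet, "genes",
                                    [f"f{i}" for i in range(400)])
        res = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        n_over = (res["direction"] == "over").sum()
        n_under = (res["direction"] == "under").sum()
        assert n_over + n_under == res["is_de"].sum()

    def test_threshold_monotonicity(self, design):
        sheet, _ = design
        cfg = h.SimConfig(frac_de_genes=0.2, seed=13)
        counts, _ = simulate_counts(cfg, sheet, "genes",
                                    [f"f{i}" for i in range(400)])
        n_de = [
            h.nb_wald_test(counts, sheet, h.DgeParams(logfc_threshold=t))["is_de"].sum()
            for t in (1.0, 2.0, 2.5, 3.5)
        ]
        assert n_de == sorted(n_de, reverse=True)

    def test_cross_check_against_statsmodels_nb_glm(self, design):
        """Independent route: statsmodels NB GLM with the same dispersion and
        contrast should produce closely matching log2FC and Wald z."""
        sm = pytest.importorskip("statsmodels.api")
        sheet, _ = design
        cfg = h.SimConfig(frac_de_genes=0.2, dispersion=0.05, seed=17)
        counts, _ = simulate_counts(cfg, sheet, "genes",
                                    [f"f{i}" for i in range(60)])
        res = h.nb_wald_test(counts, sheet, h.GENE_PARAMS)
        sf = h.size_factors(counts).to_numpy()
        crosses = pd.get_dummies(pd.Series(sheet.crosses), dtype=float)
        X = crosses[["PP", "CC", "PC", "CP"]].to_numpy()
        L = np.array([-0.5, -0.5, 0.5, 0.5])
        lfc_sm = []
        for i in range(len(res)):
            y = counts.df.iloc[i].to_numpy()
            alpha = max(res["dispersion"].iloc[i], 1e-6)
            fit = sm.GLM(
                y, X, offset=np.log(sf),
                family=sm.families.NegativeBinomial(alpha=alpha),
            ).fit()
            lfc_sm.append(float(L @ fit.params) / np.log(2))
        assert np.corrcoef(res["log2fc"], lfc_sm)[0, 1] > 0.999
        assert np.allclose(res["log2fc"], lfc_sm, atol=0.15)


class TestWilcoxon:
    def test_exact_textbook_case(self):
        # 2 of the 20 rank assignments are as extreme as the observed one
        _, p = h.wilcoxon_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_ranksum_p([1, 2, 3], [4, 5, 6]))

    def test_identical_samples_p_one(self):
        _, p = h.wilcoxon_compare([3.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=4).tolist()
            y = rng.normal(size=5).tolist()
            _, p = h.wilcoxon_compare(x, y)
            assert p == pytest.approx(exact_ranksum_p(x, y))

    def test_approximation_close_to_exact_for_small_n(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.normal(size=6).tolist()
            y = rng.normal(size=6).tolist()
            _, p_exact = h.wilcoxon_compare(x, y)  # n+m=12 -> exact
            p_oracle = exact_ranksum_p(x, y)
            assert p_exact == pytest.approx(p_oracle)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            h.wilcoxon_compare([], [1.0])
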