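"""Screen-statistics contracts: hit-rate arithmetic, the per-line efficiency
false-negative model, expression-bin rates, box-plot group tests, and the
two-reporter specificity classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnakit.screenstats import (DetectionModel, box_outliers,
                                  classify_pathway_specificity,
                                  estimate_detection, fn_bruteforce,
                                  group_fold_changes, phenotype_by_bin,
                                  summarize_screen)


def _records(staining_by_gene, morphology="wild_type"):
    rows = []
    for gene, stains in staining_by_gene.items():
        for i, s in enumerate(stains):
            rows.append({"gene_id": gene, "line_id": f"{gene}.L{i}",
                         "staining": s, "morphology": morphology})
    return pd.DataFrame(rows)


class TestSummarizeScreen:
    def test_hit_percentages_from_counts(self):
        genes = {f"g{i}": [5] for i in range(49)}
        genes.update({f"w{i}": [1] for i in range(144 - 49)})
        s = summarize_screen(_records(genes), tested_gene_total=6818,
                             expressed_gene_total=7257)
        assert s["n_any_staining"] == 144
        assert round(s["pct_any_staining"]) == 2
        assert s["n_strong_range"] == 49
        assert round(s["pct_strong_range"], 1) == 0.7
        assert round(s["coverage_pct"]) == 94

    def test_no_records_all_zero(self):
        s = summarize_screen(pd.DataFrame(columns=["gene_id", "line_id",
                                                   "staining", "morphology"]),
                             tested_gene_total=100, expressed_gene_total=100)
        assert s["pct_any_staining"] == 0
        assert s["pct_strong_range"] == 0

    def test_independent_tally(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": list(rng.integers(0, 6, size=2)) for i in range(200)}
        s = summarize_screen(_records(genes), 200, 250)
        expect_any = sum(max(v) > 0 for v in genes.values())
        expect_strong = sum(max(v) >= 4 for v in genes.values())
        assert s["n_any_staining"] == expect_any
        assert s["n_strong_range"] == expect_strong


class TestDetectionModel:
    def test_perfect_lines_never_miss(self):
        m = DetectionModel(p=1.0)
        assert m.fn(1) == 0 and m.fn(4) == 0

    def test_single_line_definition(self):
        assert DetectionModel(p=0.83).fn(1) == pytest.approx(0.17)

    def test_two_line_model(self):
        assert DetectionModel(p=0.83).fn(2) == pytest.approx(0.0289)

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.83, 1.0])
    @pytest.mark.parametrize("n", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_enumeration(self, p, n):
        assert DetectionModel(p=p).fn(n) == pytest.approx(fn_bruteforce(p, n))

    def test_fn_strictly_decreasing_in_n(self):
        m = DetectionModel(p=0.6)
        vals = [m.fn(n) for n in range(5)]
        assert vals[0] == 1.0
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_estimate_from_control_records(self):
        # 83 genes x 2 lines; 138/166 lines effective -> p ~ 0.831
        rows = []
        k = 0
        for g in range(83):
            for l in range(2):
                eff = k < 138
                rows.append({"gene_id": f"rp{g}", "line_id": f"rp{g}.{l}",
                             "staining": 0,
                             "morphology": "rudimentary" if eff else "wild_type"})
                k += 1
        model = estimate_detection(pd.DataFrame(rows))
        assert model.p == pytest.approx(138 / 166)
        assert model.fn(2) == pytest.approx((1 - 138 / 166) ** 2)
        # genes 0..68 have both lines effective, genes 69..82 have none
        assert model.empirical_gene_miss_rate == pytest.approx(14 / 83)

    def test_empty_control_set_fails(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_detection(pd.DataFrame(columns=["gene_id", "line_id",
                                                     "staining", "morphology"]))


class TestPhenotypeByBin:
    def test_uniform_phenotype_every_bin_full(self):
        genes = [f"g{i}" for i in range(40)]
        flags = pd.Series(True, index=genes)
        expr = pd.Series(np.linspace(2, 50, 40), index=genes)
        out = phenotype_by_bin(flags, expr, n_bins=4)
        assert (out["pct"] == 100.0).all()

    def test_top_bin_concentration(self):
        """20 genes, 2 bins, phenotype only in the top-10 expression genes."""
        genes = [f"g{i}" for i in range(20)]
        expr = pd.Series(np.arange(1, 21, dtype=float), index=genes)
        flags = pd.Series(expr >= 11, index=genes)
        out = phenotype_by_bin(flags, expr, n_bins=2).set_index("bin")
        assert out.loc[1, "pct"] == 0.0
        assert out.loc[2, "pct"] == 100.0

    def test_below_cutoff_genes_fall_in_bin_zero(self):
        genes = [f"g{i}" for i in range(12)]
        expr = pd.Series([0.1] * 4 + list(np.linspace(1, 9, 8)), index=genes)
        flags = pd.Series(False, index=genes)
        out = phenotype_by_bin(flags, expr, n_bins=2).set_index("bin")
        assert out.loc[0, "n_genes"] == 4

    def test_too_many_bins_fails(self):
        flags = pd.Series([True] * 3, index=["a", "b", "c"])
        expr = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="n_bins"):
            phenotype_by_bin(flags, expr, n_bins=5)

    def test_uniform_random_rate_recovered(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(6820)]
        expr = pd.Series(rng.uniform(1, 100, size=6820), index=genes)
        flags = pd.Series(rng.random(6820) < 0.3, index=genes)
        out = phenotype_by_bin(flags, expr, n_bins=10)
        se = np.sqrt(0.3 * 0.7 / 682)
        assert (np.abs(out["pct"] / 100 - 0.3) <= 3 * se).all()


class TestGroupFoldChanges:
    def test_identical_group_vs_reference(self):
        vals = pd.Series(np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)])
        labels = pd.Series(["ctrl"] * 10 + ["kd"] * 10)
        out = group_fold_changes(vals, labels, "ctrl").set_index("group")
        assert out.loc["kd", "median"] == out.loc["ctrl", "median"]
        assert out.loc["kd", "p_vs_reference"] > 0.9

    def test_iqr_outlier_rule(self):
        assert list(box_outliers([1, 2, 3, 4, 100])) == [100]
        out = group_fold_changes(pd.Series([1.0, 2, 3, 4, 100]),
                                 pd.Series(["g"] * 5), "g").iloc[0]
        assert out["median"] == 3
        assert out["n_outliers"] == 1

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal(1.0, 0.3, size=30)
        shifted = rng.normal(4.0, 0.8, size=30)
        vals = pd.Series(np.r_[ctrl, shifted])
        labels = pd.Series(["ctrl"] * 30 + ["strong"] * 30)
        out = group_fold_changes(vals, labels, "ctrl").set_index("group")
        assert out.loc["strong", "p_vs_reference"] < 0.01

    def test_missing_reference_fails(self):
        with pytest.raises(ValueError, match="reference"):
            group_fold_changes(pd.Series([1.0]), pd.Series(["a"]), "nope")


class TestSpecificity:
    @pytest.mark.parametrize("soma,germ,expect", [
        (5, 0, "soma-specific"),
        (3, 3, "common"),
        (0, 4, "germline-specific"),
        (2, "not-assayable", "not-interpretable"),
        (1, 0, "not-interpretable"),
    ])
    def test_rules(self, soma, germ, expect):
        assert classify_pathway_specificity(soma, germ) == expect

    def test_invalid_ordinal_fails(self):
        with pytest.raises(ValueError):
            classify_pathway_specificity(9, 0)

    @given(st.integers(0, 5), st.integers(0, 5))
    @settings(deadline=None, derandomize=True)
    def test_total_rule_coverage(self, soma, germ):
        got = classify_pathway_specificity(soma, germ)
        assert got in ("soma-specific", "common", "germline-specific",
                       "not-interpretable")
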