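import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicweaver.io_core import ExpressionMatrix, SampleTable, TargetTable, ValidationError
from omicweaver.coexpression import CoexpressionParams, ModuleSet
from omicweaver.mirna import (
    annotate_predicted_targets, correlate_protein_mirna, grouped_fc_regression,
    match_multiomic_samples, mirna_dep_enrichment, mirna_fpkm,
    mirna_module_enrichment,
)


def count_matrix(vals, features=None, samples=None):
    vals = np.asarray(vals, float)
    features = features or [f"mir{i}" for i in range(vals.shape[0])]
    samples = samples or [f"S{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix(features, samples, vals, "mirna_counts")


class TestFpkm:
    def test_arithmetic_example(self):
        # count 10, length 1000, library 1e6 -> FPKM 10 -> log2(11)
        m = count_matrix([[10], [999990]], features=["a", "filler"])
        out = mirna_fpkm(m, {"a": 1000, "filler": 1000})
        assert out.values[0, 0] == pytest.approx(math.log2(11), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        m = count_matrix([[0, 5], [100, 100]], features=["a", "b"])
        out = mirna_fpkm(m, {"a": 100, "b": 100})
        assert out.values[0, 0] == 0.0

    def test_doubling_library_halves_fpkm(self):
        m1 = count_matrix([[10], [90]], features=["a", "b"])
        m2 = count_matrix([[10], [190]], features=["a", "b"])
        lengths = {"a": 100, "b": 100}
        f1 = 2 ** mirna_fpkm(m1, lengths).values[0, 0] - 1
        f2 = 2 ** mirna_fpkm(m2, lengths).values[0, 0] - 1
        assert f1 == pytest.approx(2 * f2, rel=1e-12)

    def test_low_expression_filtered(self):
        m = count_matrix([[0, 1, 0], [5, 5, 5]], features=["low", "ok"])
        out = mirna_fpkm(m, {"low": 100, "ok": 100})
        assert out.feature_ids == ["ok"]  # mean 1/3 <= 0.5 threshold

    def test_missing_length_dropped_with_warning(self):
        m = count_matrix([[5, 5], [9, 9]], features=["a", "b"])
        with pytest.warns(UserWarning):
            out = mirna_fpkm(m, {"a": 100})
        assert out.feature_ids == ["a"]

    def test_wrong_modality_rejected(self):
        m = ExpressionMatrix(["a"], ["s"], [[1.0]], "rna_counts")
        with pytest.raises(ValidationError):
            mirna_fpkm(m, {"a": 100})


def sample_table(dx, region="DLPFC"):
    n = len(dx)
    return SampleTable(pd.DataFrame(dict(
        sample_id=[f"S{j}" for j in range(n)], donor_id=[f"D{j}" for j in range(n)],
        dx=dx, region=region, sex="M", age=50.0, ancestry="EUR", pmi=20.0, rin=7.0)))


class TestMatching:
    def test_full_overlap_returns_cohort(self):
        s = sample_table(["CON"] * 3 + ["PTSD"] * 3 + ["MDD"] * 2)
        prot = ExpressionMatrix(["p"], s.sample_ids, np.zeros((1, 8)),
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], s.sample_ids, np.zeros((1, 8)), "mirna_log2fpkm")
        matched = match_multiomic_samples(prot, mir, s, "PTSD", "DLPFC")
        assert matched == [f"S{j}" for j in range(6)]  # MDD excluded

    def test_partial_overlap_intersects(self):
        s = sample_table(["CON"] * 4 + ["PTSD"] * 4)
        prot = ExpressionMatrix(["p"], s.sample_ids, np.zeros((1, 8)),
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], s.sample_ids[:5], np.zeros((1, 5)),
                               "mirna_log2fpkm")
        matched = match_multiomic_samples(prot, mir, s, "PTSD", "DLPFC")
        assert matched == s.sample_ids[:5]

    def test_wrong_region_errors(self):
        s = sample_table(["CON"] * 3 + ["PTSD"] * 3)
        prot = ExpressionMatrix(["p"], s.sample_ids, np.zeros((1, 6)),
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], s.sample_ids, np.zeros((1, 6)), "mirna_log2fpkm")
        with pytest.raises(ValidationError):
            match_multiomic_samples(prot, mir, s, "PTSD", "sgPFC")


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 10)
        prot = ExpressionMatrix(["p"], [f"S{j}" for j in range(10)], -v[None, :],
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], [f"S{j}" for j in range(10)], v[None, :],
                               "mirna_log2fpkm")
        g = correlate_protein_mirna(prot, mir)
        edge = g.edges.iloc[0]
        assert edge["r"] == pytest.approx(-1.0, abs=1e-9)
        assert edge["p"] < 1e-10 and edge["significant"]

    def test_null_pairs_calibrated(self):
        rng = np.random.default_rng(1)
        n = 30
        prot = ExpressionMatrix([f"p{i}" for i in range(200)],
                                [f"S{j}" for j in range(n)],
                                rng.normal(0, 1, (200, n)), "protein_log_intensity")
        mir = ExpressionMatrix([f"m{i}" for i in range(50)],
                               [f"S{j}" for j in range(n)],
                               rng.normal(0, 1, (50, n)), "mirna_log2fpkm")
        g = correlate_protein_mirna(prot, mir)
        assert len(g.edges) == 10000
        assert 0.035 < g.edges["significant"].mean() < 0.065

    def test_constant_protein_untested(self):
        prot = ExpressionMatrix(["p"], [f"S{j}" for j in range(10)],
                                np.full((1, 10), 3.0), "protein_log_intensity")
        mir = ExpressionMatrix(["m"], [f"S{j}" for j in range(10)],
                               np.arange(10, dtype=float)[None, :], "mirna_log2fpkm")
        g = correlate_protein_mirna(prot, mir)
        assert len(g.edges) == 0

    def test_missing_protein_values_use_pairwise_complete(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, 12)
        vals = (2 * v)[None, :].copy()
        vals[0, :3] = np.nan
        prot = ExpressionMatrix(["p"], [f"S{j}" for j in range(12)], vals,
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], [f"S{j}" for j in range(12)], v[None, :],
                               "mirna_log2fpkm")
        g = correlate_protein_mirna(prot, mir)
        edge = g.edges.iloc[0]
        assert edge["n"] == 9
        assert edge["r"] == pytest.approx(1.0, abs=1e-9)

    def test_dx_adjustment_removes_shared_group_shift(self):
        rng = np.random.default_rng(3)
        n = 40
        dx = np.array([0.0] * 20 + [1.0] * 20)
        prot_v = 2.0 * dx + rng.normal(0, 1, n)
        mir_v = 1.5 * dx + rng.normal(0, 1, n)
        prot = ExpressionMatrix(["p"], [f"S{j}" for j in range(n)], prot_v[None, :],
                                "protein_log_intensity")
        mir = ExpressionMatrix(["m"], [f"S{j}" for j in range(n)], mir_v[None, :],
                               "mirna_log2fpkm")
        raw = correlate_protein_mirna(prot, mir).edges.iloc[0]["r"]
        part = correlate_protein_mirna(prot, mir, adjust=dx[:, None]).edges.iloc[0]["r"]
        assert raw > 0.3
        assert abs(part) < 0.3


def make_graph(edges_spec, universe):
    """edges_spec: list of (mirna, protein, r, p)."""
    edges = pd.DataFrame(edges_spec, columns=["mirna_id", "protein_id", "r", "p"])
    edges["n"] = 20
    edges["significant"] = edges["p"] < 0.05
    mirnas = sorted(set(edges["mirna_id"]))
    from omicweaver.mirna import ConnectionGraph
    return ConnectionGraph(edges, "test", {m: set(universe) for m in mirnas})


class TestDepEnrichment:
    def test_exact_hypergeometric_construction(self):
        # universe 500, 40 DEPs; miRNA connected to exactly the 20 planted DEPs
        universe = [f"p{i}" for i in range(500)]
        deps = {p: i < 40 for i, p in enumerate(universe)}
        rows = [("m1", f"p{i}", -0.5, 0.001) for i in range(20)]
        # sub-threshold edges for the rest of the universe
        g = make_graph(rows, universe)
        tab = mirna_dep_enrichment(g, deps)
        k, q, s, U = 20, 20, 40, 500
        expect = sum(math.comb(s, x) * math.comb(U - s, q - x)
                     for x in range(k, min(q, s) + 1)) / math.comb(U, q)
        assert tab.iloc[0]["p"] == pytest.approx(expect, abs=1e-12)
        assert tab.iloc[0]["significant"]

    def test_all_flags_false_gives_p_one(self):
        universe = [f"p{i}" for i in range(100)]
        g = make_graph([("m1", "p0", -0.5, 0.01)], universe)
        tab = mirna_dep_enrichment(g, {p: False for p in universe})
        assert tab.iloc[0]["p"] == pytest.approx(1.0)

    def test_no_connections_row_with_p_one(self):
        universe = [f"p{i}" for i in range(50)]
        g = make_graph([("m1", "p0", -0.1, 0.9)], universe)  # insignificant edge
        tab = mirna_dep_enrichment(g, {p: p == "p1" for p in universe})
        assert tab.iloc[0]["query_size"] == 0
        assert tab.iloc[0]["p"] == pytest.approx(1.0)

    def test_sign_follows_mirna_log2fc(self):
        universe = [f"p{i}" for i in range(50)]
        g = make_graph([("m1", "p0", -0.5, 0.01), ("m2", "p1", -0.5, 0.01)], universe)
        de = pd.DataFrame(dict(feature_id=["m1", "m2"], log2fc=[2.0, -1.0]))
        tab = mirna_dep_enrichment(g, {p: True for p in universe[:5]},
                                   mirna_de=de).set_index("mirna_id")
        assert tab.loc["m1", "sign"] == 1.0
        assert tab.loc["m2", "sign"] == -1.0
        assert tab.loc["m1", "signed_logp"] >= 0 >= tab.loc["m2", "signed_logp"]


class TestModuleEnrichment:
    def _mods(self, assignment):
        return ModuleSet(assignment, pd.DataFrame(), pd.DataFrame(), CoexpressionParams())

    def test_concentrated_connections_maximal_or(self):
        universe = [f"p{i}" for i in range(200)]
        assignment = {p: "blue" if i < 30 else "grey" for i, p in enumerate(universe)}
        rows = [("m1", f"p{i}", -0.6, 0.01) for i in range(15)]  # half of blue
        g = make_graph(rows, universe)
        tab = mirna_module_enrichment(g, self._mods(assignment))
        row = tab.iloc[0]
        assert row["overlap"] == 15 and row["p"] < 1e-12
        assert row["mean_module_r"] == pytest.approx(-0.6)

    def test_agrees_with_generic_fisher(self):
        from omicweaver.enrichment import fisher_test_greater

        rng = np.random.default_rng(4)
        universe = [f"p{i}" for i in range(300)]
        assignment = {p: "blue" if i < 50 else "grey" for i, p in enumerate(universe)}
        connected = rng.choice(universe, 60, replace=False)
        rows = [("m1", p, -0.4, 0.01) for p in connected]
        g = make_graph(rows, universe)
        tab = mirna_module_enrichment(g, self._mods(assignment)).iloc[0]
        k = len(set(connected) & {p for p, m in assignment.items() if m == "blue"})
        p, orr = fisher_test_greater(k, 60, 50, 300)
        assert tab["p"] == pytest.approx(p, abs=1e-12)
        assert tab["odds_ratio"] == pytest.approx(orr, abs=1e-12)


class TestAnnotateTargets:
    def test_flags_and_idempotence(self):
        universe = [f"p{i}" for i in range(10)]
        g = make_graph([("m1", "p0", -0.5, 0.01), ("m1", "p1", 0.2, 0.5)], universe)
        tt = TargetTable(pd.DataFrame(dict(
            mirna_id=["m1", "m1", "m1"], target_id=["p0", "p0", "p5"],
            source=["targetscan", "targetscan", "mirbase"])))
        out = annotate_predicted_targets(g, tt)
        assert out.edges.loc[out.edges["protein_id"] == "p0", "predicted"].iloc[0]
        assert not out.edges.loc[out.edges["protein_id"] == "p1", "predicted"].iloc[0]
        again = annotate_predicted_targets(out, tt)
        pd.testing.assert_series_equal(out.edges["predicted"], again.edges["predicted"])

    def test_empty_table_all_false(self):
        universe = [f"p{i}" for i in range(5)]
        g = make_graph([("m1", "p0", -0.5, 0.01)], universe)
        tt = TargetTable(pd.DataFrame(columns=["mirna_id", "target_id", "source"]))
        out = annotate_predicted_targets(g, tt)
        assert not out.edges["predicted"].any()


class TestGroupedRegression:
    def test_exact_negative_relation(self):
        x = np.linspace(-2, 2, 10)
        pairs = pd.DataFrame(dict(feature_id=[f"p{i}" for i in range(10)],
                                  rna_log2fc=x, protein_log2fc=-x))
        out = grouped_fc_regression(pairs, {f"p{i}": True for i in range(10)})
        row = out.set_index("group").loc["mirna_associated"]
        assert row["slope"] == pytest.approx(-1.0)
        assert row["r"] == pytest.approx(-1.0)
        not_row = out.set_index("group").loc["not_associated"]
        assert not not_row["defined"]

    def test_identical_groups_give_identical_fits(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.3, 40)
        ids = [f"p{i}" for i in range(40)]
        pairs = pd.DataFrame(dict(feature_id=ids, rna_log2fc=x, protein_log2fc=y))
        group = {f: i < 20 for i, f in enumerate(ids)}
        # swap labels: the computation must be label-symmetric
        out1 = grouped_fc_regression(pairs, group).set_index("group")
        out2 = grouped_fc_regression(pairs, {f: not v for f, v in group.items()}
                                     ).set_index("group")
        assert out1.loc["mirna_associated", "slope"] == pytest.approx(
            out2.loc["not_associated", "slope"])

    def test_degenerate_variance_flagged(self):
        pairs = pd.DataFrame(dict(feature_id=["a", "b", "c"],
                                  rna_log2fc=[1.0, 1.0, 1.0],
                                  protein_log2fc=[0.1, 0.2, 0.3]))
        out = grouped_fc_regression(pairs, {"a": True, "b": True, "c": True})
        assert not out.set_index("group").loc["mirna_associated", "defined"]
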