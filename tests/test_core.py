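"""C statistic, CICc ranking, path estimation and model averaging."""

import itertools
import math

import numpy as np
import pytest

import macropath as mp
from macropath.core import ComparisonRow

from conftest import COMMON, MODELS


class TestCStatistic:
    def test_all_ones_give_zero(self):
        assert mp.c_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_hand_value(self):
        assert mp.c_statistic([0.5, 0.1]) == pytest.approx(5.991465, abs=1e-6)

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_exp_minus_one_closed_form(self, k):
        assert mp.c_statistic([math.exp(-1)] * k) == pytest.approx(2 * k)

    def test_log_path_handles_underflow(self):
        # p ~ exp(-800) underflows to 0 as a float; the log path must not
        assert mp.c_statistic(log_ps=[-800.0]) == pytest.approx(1600.0)

    def test_zero_p_rejected_on_linear_path(self):
        with pytest.raises(ValueError, match="log_ps"):
            mp.c_statistic([0.0, 0.5])


class TestCPValue:
    def test_zero_c_gives_one(self):
        assert mp.c_pvalue(0.0, 5) == 1.0

    def test_no_claims_give_one(self):
        assert mp.c_pvalue(3.0, 0) == 1.0

    def test_chi_square_reference(self):
        # 2k degrees of freedom; checked against the chi-square upper tail
        from scipy import stats

        assert mp.c_pvalue(19.205, 8) == pytest.approx(stats.chi2.sf(19.205, 16))


class TestCICc:
    def test_hand_value(self):
        assert mp.cicc(0.0, 1, 10) == pytest.approx(2.5)

    def test_small_sample_error(self):
        with pytest.raises(ValueError, match="sample too small"):
            mp.cicc(1.0, 9, 10)


class TestCompareModels:
    def _rows(self, ciccs):
        return [
            ComparisonRow(model=f"m{i}", k=1, q=1, C=0.0, p=1.0, CICc=c)
            for i, c in enumerate(ciccs)
        ]

    def test_single_model(self):
        (row,) = mp.compare_models(self._rows([5.0]))
        assert (row.delta, row.l, row.w) == (0.0, 1.0, 1.0)

    def test_two_deltas_hand_weights(self):
        rows = mp.compare_models(self._rows([10.0, 12.0]))
        assert rows[0].w == pytest.approx(0.731, abs=5e-4)
        assert rows[1].w == pytest.approx(0.269, abs=5e-4)

    def test_weights_sum_to_one_and_sorted(self):
        rows = mp.compare_models(self._rows([30.0, 10.0, 11.0, 100.0]))
        assert sum(r.w for r in rows) == pytest.approx(1.0)
        assert [r.CICc for r in rows] == sorted(r.CICc for r in rows)
        assert rows[0].delta == 0.0 and rows[0].l == 1.0
        ls = [r.l for r in rows]
        assert ls == sorted(ls, reverse=True)

    def test_ties_broken_by_name(self):
        rows = mp.compare_models(self._rows([5.0, 5.0]))
        assert [r.model for r in rows] == ["m0", "m1"]


@pytest.fixture(scope="module")
def mammal_run():
    """A full analysis of the four-model set on simulated 'indirect' data."""
    ms = mp.parse_model_set(MODELS, common=COMMON)
    true = mp.CausalDAG.from_formulas(MODELS["indirect"] + COMMON)
    spec = mp.SimulationSpec(
        tree_size=120, dag=true,
        path_coefficients={e: 0.5 for e in true.graph.edges},
        residual_sd={v: 0.7 for v in true.vertices},
        lambda_true=0.8, seed=42,
    )
    tree = mp.simulate_tree(120, seed=42)
    data = mp.simulate_dag_traits(spec, tree)
    return mp.phylo_path(ms, data, tree)


class TestPhyloPath:
    def test_each_unique_statement_fitted_once(self, mammal_run):
        assert mammal_run.total_statements == 36
        assert len(mammal_run.fits) == 18

    def test_summary_shape_and_counts(self, mammal_run):
        summary = mammal_run.summary()
        assert list(summary.columns) == [
            "model", "k", "q", "C", "p", "CICc", "delta_CICc", "l", "w"
        ]
        by_model = summary.set_index("model")
        assert by_model.loc["null", "k"] == 11
        assert by_model.loc["both", "q"] == 21

    def test_shared_statement_shares_fit(self, mammal_run):
        d_null = mammal_run.d_sep("null").set_index("d_sep")
        d_direct = mammal_run.d_sep("direct").set_index("d_sep")
        shared = d_null.index.intersection(d_direct.index)
        assert len(shared) > 0
        for stmt in shared:
            assert d_null.loc[stmt, "p"] == d_direct.loc[stmt, "p"]

    def test_dsep_table_columns(self, mammal_run):
        table = mammal_run.d_sep("null")
        assert list(table.columns) == ["d_sep", "p", "phylo_par"]
        assert len(table) == 11
        assert table["p"].between(0, 1).all()
        assert table["phylo_par"].between(0, 1).all()

    def test_banner_reports_counts(self, mammal_run):
        banner = mammal_run.banner()
        assert "Containing 36 phylogenetic regressions, of which 18 unique" in banner
        assert "Continuous:" in banner

    def test_complete_dag_has_no_claims(self):
        formulas = [f"{b}~{a}" for a, b in itertools.combinations("ABC", 2)]
        ms = mp.parse_model_set({"full": formulas})
        dag = ms.models["full"]
        spec = mp.SimulationSpec(
            40, dag, {e: 0.3 for e in dag.graph.edges},
            {v: 0.8 for v in dag.vertices}, seed=5,
        )
        tree = mp.simulate_tree(40, seed=5)
        data = mp.simulate_dag_traits(spec, tree)
        result = mp.phylo_path(ms, data, tree)
        row = result.rows[0]
        assert (row.k, row.C, row.p) == (0, 0.0, 1.0)

    def test_json_export_roundtrips(self, mammal_run):
        import json

        payload = json.loads(mammal_run.to_json())
        assert payload["n"] == 120
        assert len(payload["summary"]) == 4


class TestEstimation:
    def test_chain_fits_one_regression_per_child(self, chain_fit_data):
        dag = mp.CausalDAG.from_formulas(["B~A", "C~B"])
        spec = mp.SimulationSpec(
            80, dag, {("A", "B"): 0.8, ("B", "C"): 0.8},
            {"A": 1.0, "B": 0.6, "C": 0.6}, seed=3,
        )
        tree = mp.simulate_tree(80, seed=3)
        data = mp.simulate_dag_traits(spec, tree)
        fitted = mp.est_dag(
            dag, data, mp.phylo_covariance(tree),
            mp.detect_variable_kinds(data),
        )
        assert set(fitted.coefficients) == {("A", "B"), ("B", "C")}

    def test_recovers_simulated_slope(self, chain_fit_data):
        dag, tree, data = chain_fit_data
        fitted = mp.est_dag(
            dag, data, mp.phylo_covariance(tree),
            mp.detect_variable_kinds(data),
        )
        beta = fitted.coefficients[("A", "B")]
        se = fitted.std_errors[("A", "B")]
        assert abs(beta - 1.0) < 2 * se

    def test_edgeless_dag_has_no_coefficients(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from("AB")
        dag = mp.CausalDAG(g, ("A", "B"))
        tree = mp.simulate_tree(20, seed=1)
        rng = np.random.default_rng(2)
        data = mp.simulate_dag_traits(
            mp.SimulationSpec(20, dag, {}, {"A": 1.0, "B": 1.0}, seed=2), tree
        )
        fitted = mp.est_dag(
            dag, data, mp.phylo_covariance(tree), mp.detect_variable_kinds(data)
        )
        assert fitted.coefficients == {}

    def test_best_is_top_ranked_and_choice_delegates(self, mammal_run):
        top_name = mammal_run.rows[0].model
        b = mp.best(mammal_run)
        c = mp.choice(mammal_run, top_name)
        assert b.coefficients == c.coefficients

    def test_choice_unknown_name_lists_models(self, mammal_run):
        with pytest.raises(KeyError, match="indirect"):
            mp.choice(mammal_run, "missing")

    def test_bootstrap_brackets_estimate(self, chain_fit_data):
        dag, tree, data = chain_fit_data
        fitted = mp.est_dag(
            dag, data, mp.phylo_covariance(tree),
            mp.detect_variable_kinds(data), boot=30, seed=9,
        )
        edge = ("A", "B")
        lo, hi = fitted.ci_lower[edge], fitted.ci_upper[edge]
        assert lo < fitted.coefficients[edge] < hi
        assert hi - lo > 0


class TestAveraging:
    def test_conditional_keeps_unshared_path_full_shrinks_it(self, mammal_run):
        full = mp.average(mammal_run, avg_method="full", cut_off=np.inf)
        cond = mp.average(mammal_run, avg_method="conditional", cut_off=np.inf)
        fits = {r.model: mp.choice(mammal_run, r.model) for r in mammal_run.rows}
        weights = {r.model: r.w for r in mammal_run.rows}
        # direct brain-size path exists only in 'direct' and 'both'
        edge = ("Br", "Status")
        carriers = [m for m in fits if edge in fits[m].coefficients]
        assert set(carriers) == {"direct", "both"}
        expected_full = sum(weights[m] * fits[m].coefficients[edge] for m in carriers)
        wsum = sum(weights[m] for m in carriers)
        expected_cond = expected_full / wsum
        assert full.coefficients[edge] == pytest.approx(expected_full)
        assert cond.coefficients[edge] == pytest.approx(expected_cond)
        assert abs(full.coefficients[edge]) <= abs(cond.coefficients[edge])

    def test_identical_models_are_a_fixed_point(self):
        ms = mp.parse_model_set({"m1": ["B~A"], "m2": ["B~A"]})
        dag = ms.models["m1"]
        spec = mp.SimulationSpec(60, dag, {("A", "B"): 0.7},
                                 {"A": 1.0, "B": 0.7}, seed=8)
        tree = mp.simulate_tree(60, seed=8)
        data = mp.simulate_dag_traits(spec, tree)
        result = mp.phylo_path(ms, data, tree)
        averaged = mp.average(result, avg_method="full", cut_off=np.inf)
        single = mp.choice(result, "m1")
        assert averaged.coefficients[("A", "B")] == pytest.approx(
            single.coefficients[("A", "B")]
        )

    def test_full_average_bounded_by_max_model_coefficient(self, mammal_run):
        full = mp.average(mammal_run, avg_method="full", cut_off=np.inf)
        fits = {r.model: mp.choice(mammal_run, r.model) for r in mammal_run.rows}
        for edge, beta in full.coefficients.items():
            per_model = [
                abs(f.coefficients[edge])
                for f in fits.values() if edge in f.coefficients
            ]
            assert abs(beta) <= max(per_model) + 1e-12

    def test_cut_off_two_selects_close_models(self, mammal_run):
        included = [r for r in mammal_run.rows if r.delta <= 2.0]
        averaged = mp.average(mammal_run, avg_method="conditional", cut_off=2.0)
        union_edges = set()
        for r in included:
            union_edges |= set(
                mammal_run.model_set.models[r.model].graph.edges
            )
        assert set(averaged.coefficients) == union_edges

    def test_no_model_within_cutoff_raises(self, mammal_run):
        with pytest.raises(ValueError, match="cut_off"):
            mp.average(mammal_run, cut_off=-1.0)

    def test_warns_on_significant_models(self, mammal_run, caplog):
        with caplog.at_level("WARNING", logger="macropath"):
            mp.average(mammal_run, avg_method="full", cut_off=np.inf)
        assert "significant C statistic" in caplog.text
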