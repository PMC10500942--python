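import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgrm import synthetic
from cgrm.logictrn import (
    KineticParams,
    TFLogic,
    combine_binding,
    enumerate_logics,
    fit_logic,
    infer_trn,
    logic_confidence,
    rate_proxy,
    transcription_rate,
)
from tests.conftest import all_up_degs


class TestTFLogic:
    def test_and_or_canonicalized_not_order_sensitive(self):
        assert TFLogic("AND", ("B", "A")) == TFLogic("AND", ("A", "B"))
        assert TFLogic("NOT", ("B", "A")) != TFLogic("NOT", ("A", "B"))

    def test_string_notation_round_trip(self):
        for text in ("GATA4", "GATA4 & MESP1", "GATA4 | MESP1", "MESP1 > SOX2"):
            assert str(TFLogic.from_string(text)) == text

    def test_operand_arity_enforced(self):
        with pytest.raises(ValueError):
            TFLogic("SINGLE", ("A", "B"))
        with pytest.raises(ValueError):
            TFLogic("AND", ("A",))


class TestTranscriptionRate:
    def test_zero_occupancy_gives_zero_rate(self):
        assert transcription_rate(KineticParams(1, 1), 0.0) == 0.0

    def test_rate_saturates_at_i_max(self):
        rate = transcription_rate(KineticParams(2, 1), 1000.0)
        assert 2 - rate < 1e-12

    def test_closed_form_matches_series_oracle(self):
        # 1 - 1/e at I_max = k_b = y = 1
        closed = transcription_rate(KineticParams(1, 1), 1.0)
        assert closed == pytest.approx(1 - np.exp(-1), abs=1e-15)
        series = transcription_rate(KineticParams(1, 1), 1.0, mode="series", n_terms=30)
        assert abs(closed - series) < 1e-12

    def test_closed_form_matches_converged_series_across_grid(self):
        # enough terms for the largest u on the grid
        for i_max in (0.5, 1.0, 4.0):
            for k_b in (0.2, 1.0, 3.0):
                for y in np.linspace(0, 1, 9):
                    closed = transcription_rate(KineticParams(i_max, k_b), y)
                    series = transcription_rate(
                        KineticParams(i_max, k_b), y, mode="series", n_terms=60
                    )
                    assert abs(closed - series) < 1e-12

    def test_rate_monotone_in_occupancy_and_bounded(self):
        params = KineticParams(3.0, 2.0)
        ys = np.linspace(0, 1, 50)
        rates = transcription_rate(params, ys)
        assert np.all(np.diff(rates) >= 0)
        assert np.all(rates <= params.i_max)

    def test_negative_occupancy_rejected(self):
        with pytest.raises(ValueError):
            transcription_rate(KineticParams(1, 1), -0.1)


class TestCombineBinding:
    @pytest.mark.parametrize(
        "op,y1,y2,expected",
        [
            ("SINGLE", 0.7, None, 0.7),
            ("AND", 1.0, 1.0, 1.0),
            ("AND", 0.9, 0.0, 0.0),
            ("OR", 0.5, 0.5, 0.75),
            ("NOT", 0.8, 1.0, 0.0),
            ("NOT", 0.8, 0.0, 0.8),
        ],
    )
    def test_boolean_algebra_examples(self, op, y1, y2, expected):
        ops = ("A",) if op == "SINGLE" else ("A", "B")
        assert combine_binding(TFLogic(op, ops), y1, y2) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60)
    @given(
        op=st.sampled_from(["AND", "OR", "NOT"]),
        y1=st.floats(0, 1),
        y2=st.floats(0, 1),
    )
    def test_combined_occupancy_stays_in_unit_interval(self, op, y1, y2):
        out = combine_binding(TFLogic(op, ("A", "B")), y1, y2)
        assert 0.0 <= out <= 1.0

    def test_missing_operand_rejected(self):
        with pytest.raises(ValueError):
            combine_binding(TFLogic("AND", ("A", "B")), 0.5)


class TestEnumerateLogics:
    @pytest.mark.parametrize("n_tfs,expected", [(1, 1), (2, 6), (14, 378)])
    def test_candidate_counts(self, n_tfs, expected):
        # n singles + 2*C(n,2) AND/OR + P(n,2) NOT
        logics = enumerate_logics([f"T{i}" for i in range(n_tfs)])
        assert len(logics) == expected
        assert len(set(map(str, logics))) == expected

    def test_order_deterministic(self):
        a = enumerate_logics(["B", "A", "C"])
        b = enumerate_logics(["C", "A", "B"])
        assert list(map(str, a)) == list(map(str, b))


class TestFitLogic:
    def test_noiseless_closed_loop_recovers_planted_parameters(self):
        truth = synthetic.make_truth(n_genes=8, n_tfs=4, n_timepoints=11,
                                     noise_cv=0.0, seed=3)
        expr, binding, _ = synthetic.generate_expression(truth)
        act = truth.tf_activity()
        for j, gene in enumerate(truth.gene_ids):
            occ = {
                tf: act[tf] * binding.strength(tf, gene)
                for tf in truth.logics[j].operands
            }
            fit = fit_logic(expr.row(gene), expr.time_points, truth.logics[j],
                            occ, gene_id=gene, t_m=1)
            assert fit.params.i_max == pytest.approx(truth.i_max[j], rel=0.01)
            assert fit.params.k_b == pytest.approx(truth.k_b[j], rel=0.01)
            assert fit.rss < 1e-10

    def test_zero_occupancy_fit_reports_raw_rate_energy(self):
        values = np.array([1.0, 2.0, 2.5, 2.2, 3.0, 3.5])
        t = np.arange(6.0)
        fit = fit_logic(values, t, TFLogic("SINGLE", ("A",)),
                        {"A": 0.0}, t_m=1, whiten=False)
        r = rate_proxy(values, t)
        assert fit.rss == pytest.approx(np.sum(r**2))

    def test_flat_series_fits_zero_rate(self):
        values = np.full(8, 4.0)
        fit = fit_logic(values, np.arange(8.0), TFLogic("SINGLE", ("A",)),
                        {"A": np.linspace(0.1, 0.9, 8)}, t_m=1)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_too_few_usable_points_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            fit_logic(np.array([1.0, 2, 3]), np.arange(3.0),
                      TFLogic("SINGLE", ("A",)), {"A": 0.5}, t_m=1)


class TestLogicConfidence:
    def test_single_candidate_gets_full_confidence(self):
        from cgrm.logictrn import LogicFit

        fit = LogicFit("G", TFLogic("SINGLE", ("A",)), KineticParams(1, 1), 0.5, 8)
        (scored,) = logic_confidence([fit])
        assert scored.confidence == pytest.approx(1.0)

    def test_identical_rss_split_evenly_and_sum_to_one(self):
        from cgrm.logictrn import LogicFit

        fits = [
            LogicFit("G", TFLogic("SINGLE", (tf,)), KineticParams(1, 1), 0.2, 8)
            for tf in "AB"
        ]
        scored = logic_confidence(fits)
        assert [f.confidence for f in scored] == pytest.approx([0.5, 0.5])
        assert sum(f.confidence for f in scored) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_n_obs_rejected(self):
        from cgrm.logictrn import LogicFit

        fits = [
            LogicFit("G", TFLogic("SINGLE", ("A",)), KineticParams(1, 1), 0.2, 8),
            LogicFit("G", TFLogic("SINGLE", ("B",)), KineticParams(1, 1), 0.2, 9),
        ]
        with pytest.raises(ValueError):
            logic_confidence(fits)


@pytest.fixture(scope="module")
def planted():
    truth = synthetic.make_truth(n_genes=25, n_tfs=4, n_timepoints=11,
                                 noise_cv=0.0, seed=9)
    expr, binding, _ = synthetic.generate_expression(truth)
    return truth, expr, binding


class TestInferTRN:
    def test_noiseless_planted_logic_is_unique_confident_call(self, planted):
        truth, expr, binding = planted
        fits = infer_trn(expr, binding, all_up_degs(truth.gene_ids),
                         conf_min=0.9, tf_activity=truth.tf_activity())
        by_gene = {}
        for f in fits:
            by_gene.setdefault(f.gene_id, []).append(f)
        recovered = sum(
            len(v) == 1 and str(v[0].logic) == str(truth.logics[truth.gene_ids.index(g)])
            for g, v in by_gene.items()
        )
        assert recovered >= 24  # >= 95% of 25

    def test_conf_min_zero_reports_full_candidate_list(self, planted):
        truth, expr, binding = planted
        gene = truth.gene_ids[0]
        degs = all_up_degs([gene])
        fits = infer_trn(expr, binding, degs, conf_min=0.0,
                         tf_activity=truth.tf_activity())
        # operands of the planted pairwise logic -> 6 candidate logics
        assert len(fits) == 6
        assert sum(f.confidence for f in fits) == pytest.approx(1.0, abs=1e-9)

    def test_empty_deg_table_gives_empty_output(self, planted):
        _, expr, binding = planted
        assert infer_trn(expr, binding, all_up_degs([])) == []

    def test_gene_without_binding_skipped_not_error(self, planted, caplog):
        truth, expr, binding = planted
        import logging

        # append an unbound gene to the expression matrix
        from cgrm.io import ExpressionSeries

        expr2 = ExpressionSeries(
            expr.gene_ids + ["ORPHAN"],
            expr.time_points,
            np.vstack([expr.values, np.linspace(1, 2, expr.n_time_points)]),
        )
        with caplog.at_level(logging.INFO, logger="cgrm.logictrn"):
            fits = infer_trn(expr2, binding, all_up_degs(["ORPHAN"]),
                             tf_activity=truth.tf_activity())
        assert fits == []
        assert any("ORPHAN" in rec.message for rec in caplog.records)
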