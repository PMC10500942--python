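import math

import numpy as np
import pandas as pd
import pytest

from cgrm.deg import DEGTable
from cgrm.io import GeneSetCollection
from cgrm.logictrn import KineticParams, LogicFit, TFLogic
from cgrm.networks import (
    GRN,
    Edge,
    Node,
    assemble_grn,
    conserved_targets,
    export_network,
    heart_targets,
    import_network,
)
from cgrm.rca import InteractionResult


def _degs(rows):
    return DEGTable(pd.DataFrame(rows, columns=["gene_id", "log2_fold_change",
                                                "p_value", "direction"]))


@pytest.fixture
def single_evidence_inputs():
    degs = _degs([("G1", 2.0, 0.01, "up")])
    fit = LogicFit("G1", TFLogic("SINGLE", ("GATA4",)), KineticParams(1, 1),
                   0.01, 8, confidence=0.95)
    rca = InteractionResult(
        ["G1"], ["miR-1"], np.array([[0.8]]), np.array([[0.002]]),
        direction_context="up",
    )
    return [fit], [rca], {"miR-1": "miRNA"}, degs


class TestAssemble:
    def test_single_tf_logic_plus_rca_edge(self, single_evidence_inputs):
        fits, rcas, classes, degs = single_evidence_inputs
        grn = assemble_grn(fits, rcas, classes, degs, stage_label="early")
        # nodes: TF GATA4, gene G1, regulator miR-1; edges: logic + rca
        assert sorted(grn.node_ids) == ["G1", "GATA4", "miR-1"]
        assert len(grn.edges) == 2
        assert {e.relation for e in grn.edges} == {"logic", "rca"}
        gene = next(n for n in grn.nodes if n.id == "G1")
        assert gene.kind == "gene" and gene.direction == "up"

    def test_pairwise_logic_becomes_first_class_node(self):
        degs = _degs([("G1", 2.0, 0.01, "up")])
        fit = LogicFit("G1", TFLogic("AND", ("GATA4", "MESP1")),
                       KineticParams(1, 1), 0.01, 8, confidence=0.93)
        grn = assemble_grn([fit], [], {}, degs)
        assert "GATA4 & MESP1" in grn.node_ids
        members = [e for e in grn.edges if e.relation == "member"]
        assert {e.target for e in members} == {"GATA4", "MESP1"}
        logic_edges = [e for e in grn.edges if e.relation == "logic"]
        assert len(logic_edges) == 1
        assert logic_edges[0].source == "GATA4 & MESP1"

    def test_empty_inputs_give_empty_grn(self):
        grn = assemble_grn([], [], {}, _degs([]))
        assert grn.nodes == [] and grn.edges == []

    def test_p_equal_alpha_excluded_strictly(self, single_evidence_inputs):
        fits, _, classes, degs = single_evidence_inputs
        boundary = InteractionResult(
            ["G1"], ["miR-1"], np.array([[0.8]]), np.array([[0.05]]),
            direction_context="up",
        )
        grn = assemble_grn([], [boundary], classes, degs, alpha=0.05)
        assert len(grn.edges) == 0

    def test_unknown_gene_in_evidence_rejected(self, single_evidence_inputs):
        fits, rcas, classes, _ = single_evidence_inputs
        with pytest.raises(ValueError, match="unknown gene"):
            assemble_grn(fits, rcas, classes, _degs([("OTHER", 1.0, 0.01, "up")]))

    def test_threshold_filtering_is_monotone(self, single_evidence_inputs):
        fits, rcas, classes, degs = single_evidence_inputs
        loose = assemble_grn(fits, rcas, classes, degs, alpha=0.05)
        tight = assemble_grn(fits, rcas, classes, degs, alpha=0.001)
        tight_edges = {(e.source, e.target, e.relation) for e in tight.edges}
        loose_edges = {(e.source, e.target, e.relation) for e in loose.edges}
        assert tight_edges <= loose_edges


class TestConservation:
    def test_common_regulator_in_reference_and_other(self):
        results = {
            "ref": [("G", "MESP1")],
            "ds2": [("G", "MESP1")],
            "ds3": [],
        }
        (rep,) = conserved_targets(results, "ref")
        assert rep.conserved and rep.regulators_shared == ["MESP1"]
        assert rep.datasets_supporting == ["ds2", "ref"]

    def test_different_regulators_do_not_conserve(self):
        results = {"ref": [("G", "MESP1")], "ds2": [("G", "GATA4")]}
        (rep,) = conserved_targets(results, "ref")
        assert not rep.conserved

    def test_reference_membership_required(self):
        results = {"ref": [], "ds2": [("G", "MESP1")], "ds3": [("G", "MESP1")]}
        assert conserved_targets(results, "ref") == []
        with pytest.raises(ValueError):
            conserved_targets(results, "missing")

    def test_adding_dataset_never_unconserves(self):
        base = {"ref": [("G", "A")], "ds2": [("G", "A")]}
        (before,) = conserved_targets(base, "ref")
        more = dict(base, ds3=[("H", "B")])
        (after,) = conserved_targets(more, "ref")
        assert before.conserved and after.conserved

    def test_min_other_two_requires_both_ipsc_datasets(self):
        results = {"ref": [("G", "A")], "ds2": [("G", "A")], "ds3": []}
        (rep,) = conserved_targets(results, "ref", min_other=2)
        assert not rep.conserved


class TestHeartTargets:
    heart = GeneSetCollection({"contraction": {"TNNT2", "MYL7"},
                               "development": {"TNNT2", "GATA4"}})

    def test_annotation_with_categories(self):
        out = heart_targets({"TNNT2", "SOX2"}, self.heart)
        assert out == {"TNNT2": ["contraction", "development"]}

    def test_disjoint_targets_empty(self):
        assert heart_targets({"SOX2"}, self.heart) == {}

    def test_output_subset_of_input(self):
        out = heart_targets({"TNNT2", "MYL7", "NANOG"}, self.heart)
        assert set(out) <= {"TNNT2", "MYL7", "NANOG"}


class TestExport:
    @pytest.fixture
    def grn(self, single_evidence_inputs):
        fits, rcas, classes, degs = single_evidence_inputs
        return assemble_grn(fits, rcas, classes, degs, stage_label="early")

    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_lossless_round_trip(self, grn, tmp_path, fmt):
        path = tmp_path / ("g.json" if fmt == "json" else "g")
        export_network(grn, path, format=fmt)
        assert import_network(path, format=fmt) == grn

    def test_empty_grn_round_trip(self, tmp_path):
        grn = GRN([], [])
        for fmt in ("tsv", "json"):
            path = tmp_path / f"empty_{fmt}"
            export_network(grn, path, format=fmt)
            assert import_network(path, format=fmt) == grn

    def test_graphml_parses_back_with_attributes(self, grn, tmp_path):
        import networkx as nx

        path = tmp_path / "g.graphml"
        export_network(grn, path, format="graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(grn.node_ids)
        assert g.nodes["G1"]["kind"] == "gene"
        assert g.number_of_edges() == len(grn.edges)

    def test_unknown_format_rejected(self, grn, tmp_path):
        with pytest.raises(ValueError):
            export_network(grn, tmp_path / "x", format="xlsx")
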