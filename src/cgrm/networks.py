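"""Assembly, conservation analysis and export of multi-regulator GRNs.

A GRN is a typed graph: nodes are TFs, miRNAs, lncRNAs, target genes, and
(for pairwise TF logics) first-class logic nodes such as ``"MESP1 & GATA4"``
whose constituent TFs are attached by membership edges. Every regulatory
edge carries its evidence — a confident logic fit or a significant
factorization interaction — so filtering evidence filters edges.

Cross-dataset conservation follows a reference-anchored rule: a (gene,
regulator) pair is conserved when it is detected in the designated
reference dataset and in at least ``min_other`` of the remaining datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .deg import DEGTable
from .io import GeneSetCollection
from .logictrn import LogicFit, TFLogic
from .rca import InteractionResult

NODE_KINDS = ("TF", "miRNA", "lncRNA", "gene", "logic")
EDGE_RELATIONS = ("logic", "rca", "member")


@dataclass(frozen=True)
class Node:
    id: str
    kind: str
    direction: str = "NA"  # up / down / NA

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.direction not in ("up", "down", "NA"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    relation: str  # logic / rca / member
    logic_string: str = ""
    confidence: float = math.nan
    strength: float = math.nan
    p: float = math.nan
    stage: str = ""
    conserved: bool = False

    def __post_init__(self) -> None:
        if self.relation not in EDGE_RELATIONS:
            raise ValueError(f"unknown edge relation {self.relation!r}")


@dataclass
class GRN:
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for e in self.edges:
            if e.source not in ids or e.target not in ids:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented

        def key(grn: "GRN"):
            edges = []
            for e in grn.edges:
                d = asdict(e)
                for k in ("confidence", "strength", "p"):
                    d[k] = "nan" if math.isnan(d[k]) else repr(round(d[k], 12))
                edges.append(tuple(sorted(d.items())))
            return sorted(map(asdict, grn.nodes), key=str), sorted(edges)

        return key(self) == key(other)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, direction=n.direction)
        for e in self.edges:
            g.add_edge(
                e.source, e.target, relation=e.relation,
                logic_string=e.logic_string, confidence=e.confidence,
                strength=e.strength, p=e.p, stage=e.stage, conserved=e.conserved,
            )
        return g


def _direction_lookup(degs: DEGTable) -> dict[str, str]:
    return dict(zip(degs.frame["gene_id"], degs.frame["direction"]))


def assemble_grn(
    logic_fits: Sequence[LogicFit],
    rca_results: Sequence[InteractionResult],
    regulator_classes: Mapping[str, str],
    degs: DEGTable,
    stage_label: str = "",
    alpha: float = 0.05,
) -> GRN:
    """Build a GRN from confident logic fits and significant interactions.

    Logic edges come from the given fits (already confidence-filtered
    upstream); factorization edges require ``p < alpha`` (strict). Gene
    direction is taken from the DEG table, which also defines the gene
    namespace: evidence naming a gene outside it is an error. Pairwise
    logics become first-class nodes with membership edges to their TFs.
    Node and edge order is deterministic.
    """
    directions = _direction_lookup(degs)
    nodes: dict[str, Node] = {}
    edges: list[Edge] = []

    def add_node(node: Node) -> None:
        # a regulator that is itself differentially expressed is one node;
        # the regulator kind wins, the DEG direction is kept
        prev = nodes.get(node.id)
        if prev is None:
            nodes[node.id] = node
        elif prev.kind != node.kind:
            if "gene" not in (prev.kind, node.kind):
                raise ValueError(f"node {node.id!r} assigned two kinds")
            kind = prev.kind if prev.kind != "gene" else node.kind
            direction = prev.direction if prev.direction != "NA" else node.direction
            nodes[node.id] = Node(node.id, kind, direction)
        elif prev.direction == "NA" and node.direction != "NA":
            nodes[node.id] = node

    def gene_node(gene: str) -> None:
        if gene not in directions:
            raise ValueError(f"evidence references unknown gene {gene!r}")
        add_node(Node(gene, "gene", directions[gene]))

    for fit in logic_fits:
        gene_node(fit.gene_id)
        logic = fit.logic
        source = str(logic)
        if logic.operator == "SINGLE":
            add_node(Node(source, "TF"))
        else:
            add_node(Node(source, "logic"))
            for tf in logic.operands:
                add_node(Node(tf, "TF"))
                edges.append(Edge(source=source, target=tf, relation="member",
                                  logic_string=str(logic), stage=stage_label))
        edges.append(
            Edge(source=source, target=fit.gene_id, relation="logic",
                 logic_string=str(logic), confidence=fit.confidence,
                 stage=stage_label)
        )
    for res in rca_results:
        for i, gene in enumerate(res.gene_ids):
            for j, reg in enumerate(res.regulator_ids):
                if not res.p_values[i, j] < alpha:
                    continue
                gene_node(gene)
                kind = regulator_classes.get(reg)
                if kind is None:
                    raise ValueError(f"regulator {reg!r} has no declared class")
                add_node(Node(reg, kind))
                edges.append(
                    Edge(source=reg, target=gene, relation="rca",
                         strength=float(res.strengths[i, j]),
                         p=float(res.p_values[i, j]), stage=stage_label)
                )
    ordered_nodes = sorted(nodes.values(), key=lambda n: (n.kind, n.id))
    edges.sort(key=lambda e: (e.relation, e.source, e.target))
    return GRN(ordered_nodes, edges)


@dataclass
class ConservationReport:
    gene_id: str
    regulators_shared: list[str]
    datasets_supporting: list[str]
    conserved: bool


def conserved_targets(
    results: Mapping[str, Iterable[tuple[str, str]]],
    reference_dataset: str,
    min_other: int = 1,
) -> list[ConservationReport]:
    """Reference-anchored conservation of (gene, regulator) pairs.

    ``results`` maps dataset name -> iterable of (gene, regulator) pairs
    detected in that dataset. A pair is conserved iff it appears in the
    reference dataset and in at least ``min_other`` non-reference datasets;
    a gene is conserved iff any of its pairs is. One report per gene seen
    in the reference dataset.
    """
    if reference_dataset not in results:
        raise ValueError(f"reference dataset {reference_dataset!r} absent")
    if len(results) < 2:
        raise ValueError("conservation needs at least two datasets")
    pair_sets = {ds: set(map(tuple, pairs)) for ds, pairs in results.items()}
    others = [ds for ds in pair_sets if ds != reference_dataset]
    reports: dict[str, ConservationReport] = {}
    for gene, reg in sorted(pair_sets[reference_dataset]):
        support = [ds for ds in others if (gene, reg) in pair_sets[ds]]
        pair_ok = len(support) >= min_other
        rep = reports.get(gene)
        if rep is None:
            reports[gene] = ConservationReport(
                gene, [reg] if pair_ok else [],
                sorted({reference_dataset, *support}) if pair_ok else [reference_dataset],
                pair_ok,
            )
        elif pair_ok:
            rep.regulators_shared.append(reg)
            rep.datasets_supporting = sorted(
                set(rep.datasets_supporting) | {reference_dataset, *support}
            )
            rep.conserved = True
    return [reports[g] for g in sorted(reports)]


def heart_targets(
    targets: set[str], heart_sets: GeneSetCollection
) -> dict[str, list[str]]:
    """Targets that fall in >= 1 curated heart gene set, with category labels."""
    if not len(heart_sets):
        raise ValueError("heart gene-set collection is empty")
    out: dict[str, list[str]] = {}
    for gene in sorted(targets):
        cats = [name for name in heart_sets.names() if gene in heart_sets[name]]
        if cats:
            out[gene] = cats
    return out


# ---------------------------------------------------------------------------
# serialization


def export_network(grn: GRN, path: str | Path, format: str = "tsv") -> list[Path]:
    """Write a GRN as tsv (nodes + edges files), json, or GraphML."""
    path = Path(path)
    if format == "tsv":
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        pd.DataFrame([asdict(n) for n in grn.nodes],
                     columns=["id", "kind", "direction"]).to_csv(
            nodes_path, sep="\t", index=False)
        pd.DataFrame([asdict(e) for e in grn.edges],
                     columns=[f.name for f in Edge.__dataclass_fields__.values()]
                     ).to_csv(edges_path, sep="\t", index=False)
        return [nodes_path, edges_path]
    if format == "json":
        payload = {"nodes": [asdict(n) for n in grn.nodes],
                   "edges": [asdict(e) for e in grn.edges]}
        path.write_text(json.dumps(payload, indent=1, allow_nan=True))
        return [path]
    if format == "graphml":
        g = grn.to_networkx()
        nx.write_graphml(g, path)
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def import_network(path: str | Path, format: str = "tsv") -> GRN:
    path = Path(path)
    if format == "tsv":
        nodes_df = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t",
                               keep_default_na=False)
        edges_df = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t",
                               keep_default_na=False)
        nodes = [Node(str(r.id), r.kind, r.direction) for r in nodes_df.itertuples()]
        edges = []
        for r in edges_df.itertuples():
            edges.append(Edge(
                source=str(r.source), target=str(r.target), relation=r.relation,
                logic_string="" if r.logic_string == "" else str(r.logic_string),
                confidence=float(r.confidence) if r.confidence != "" else math.nan,
                strength=float(r.strength) if r.strength != "" else math.nan,
                p=float(r.p) if r.p != "" else math.nan,
                stage="" if r.stage == "" else str(r.stage),
                conserved=str(r.conserved) == "True",
            ))
        return GRN(nodes, edges)
    if format == "json":
        payload = json.loads(Path(path).read_text())
        nodes = [Node(**n) for n in payload["nodes"]]
        edges = [Edge(**e) for e in payload["edges"]]
        return GRN(nodes, edges)
    raise ValueError(f"unknown import format {format!r}")
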