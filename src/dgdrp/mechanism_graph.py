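"""Per-drug heterogeneous drug-mechanism graphs.

For each drug the graph joins its direct targets T_D, the indirect targets
T_I found by network propagation, all interaction edges among those genes
(no confidence cutoff — mechanism topology uses the full network), and the
pathways containing at least one indirect target, connected to their
indirect-target members. Only indirect targets link to pathway nodes;
a gene that is both a direct target and highly propagated stays labeled
direct, keeping the two sets disjoint.

Two ablation variants are supported: ``no_pathway`` drops pathway nodes and
edges, and ``ppi_only`` drops indirect targets and pathways altogether,
taking its topology from high-confidence interaction edges (combined score
above 990) plus every edge incident to a direct target.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_chem import PPINetwork, PathwayCollection, DrugCatalog, Drug
from .propagation import (PropagationConfig, propagate_from_targets,
                          select_indirect_targets)

VARIANTS = ("full", "no_pathway", "ppi_only")
PPI_ONLY_MIN_SCORE = 990

DIRECT = "direct"
INDIRECT = "indirect"


@dataclass
class MechanismGraph:
    drug_id: str
    gene_nodes: list[str]          # direct targets first, then indirect
    node_kind: list[str]           # "direct" | "indirect", parallel to gene_nodes
    pathway_nodes: list[str]
    gene_gene_edges: list[tuple[str, str]]
    gene_pathway_edges: list[tuple[str, str]]  # (indirect gene, pathway id)
    variant: str = "full"

    def __post_init__(self) -> None:
        genes = set(self.gene_nodes)
        if len(genes) != len(self.gene_nodes):
            raise ValueError(f"{self.drug_id}: duplicate gene nodes")
        for u, v in self.gene_gene_edges:
            if u not in genes or v not in genes:
                raise ValueError(f"{self.drug_id}: edge ({u}, {v}) leaves gene nodes")
        incident = {p for _, p in self.gene_pathway_edges}
        if incident != set(self.pathway_nodes):
            raise ValueError(f"{self.drug_id}: pathway node without membership edge")

    @property
    def direct_targets(self) -> list[str]:
        return [g for g, k in zip(self.gene_nodes, self.node_kind) if k == DIRECT]

    @property
    def indirect_targets(self) -> list[str]:
        return [g for g, k in zip(self.gene_nodes, self.node_kind) if k == INDIRECT]

    @property
    def n_nodes(self) -> int:
        return len(self.gene_nodes) + len(self.pathway_nodes)

    def node_order(self) -> list[tuple[str, str]]:
        """(node_id, kind) in canonical order: direct, indirect, pathway."""
        out = list(zip(self.gene_nodes, self.node_kind))
        out += [(p, "pathway") for p in self.pathway_nodes]
        return out


def build_mechanism_graph(drug: Drug, indirect_targets: list[str],
                          full_ppi: PPINetwork,
                          pathways: PathwayCollection | None,
                          variant: str = "full") -> MechanismGraph:
    """Assemble one drug's mechanism graph.

    ``indirect_targets`` come from propagation, already score-ordered;
    ``full_ppi`` is the unfiltered network. Node ordering is deterministic:
    direct targets in catalog order, indirect targets score-descending,
    pathways by ascending id.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    direct = [t for t in sorted(drug.targets) if full_ppi.has_gene(t)]
    if not direct:
        raise ValueError(f"drug {drug.drug_id}: no target on the network")

    if variant == "ppi_only":
        return _build_ppi_only(drug, direct, full_ppi)

    direct_set = set(direct)
    indirect = [g for g in indirect_targets if g not in direct_set]
    gene_nodes = direct + indirect
    node_kind = [DIRECT] * len(direct) + [INDIRECT] * len(indirect)
    gene_set = set(gene_nodes)
    gene_gene = [(u, v) for u, v, _ in full_ppi.edges_with_scores()
                 if u in gene_set and v in gene_set]
    gene_gene = _canonical_edges(gene_gene, gene_nodes)

    pathway_nodes: list[str] = []
    gene_pathway: list[tuple[str, str]] = []
    if variant == "full" and pathways is not None:
        indirect_set = set(indirect)
        for pid in sorted(p for p, _ in pathways):
            members = pathways.members(pid) & indirect_set
            if members:
                pathway_nodes.append(pid)
                order = {g: i for i, g in enumerate(gene_nodes)}
                gene_pathway += [(g, pid) for g in sorted(members, key=order.get)]
    return MechanismGraph(drug.drug_id, gene_nodes, node_kind, pathway_nodes,
                          gene_gene, gene_pathway, variant=variant)


def _build_ppi_only(drug: Drug, direct: list[str], full_ppi: PPINetwork) -> MechanismGraph:
    direct_set = set(direct)
    edges = [(u, v) for u, v, s in full_ppi.edges_with_scores()
             if s > PPI_ONLY_MIN_SCORE or u in direct_set or v in direct_set]
    nodes = set(direct)
    for u, v in edges:
        nodes.add(u)
        nodes.add(v)
    others = sorted(nodes - direct_set)
    gene_nodes = direct + others
    node_kind = [DIRECT] * len(direct) + [INDIRECT] * len(others)
    gene_gene = _canonical_edges(edges, gene_nodes)
    return MechanismGraph(drug.drug_id, gene_nodes, node_kind, [], gene_gene, [],
                          variant="ppi_only")


def _canonical_edges(edges, gene_nodes) -> list[tuple[str, str]]:
    order = {g: i for i, g in enumerate(gene_nodes)}
    canon = {tuple(sorted(e, key=order.get)) for e in edges}
    return sorted(canon, key=lambda e: (order[e[0]], order[e[1]]))


def batch_build(catalog: DrugCatalog, network_for_propagation: PPINetwork,
                full_ppi: PPINetwork, pathways: PathwayCollection | None,
                config: PropagationConfig | None = None,
                n_indirect: int = 20, variant: str = "full",
                ) -> dict[str, MechanismGraph]:
    """One mechanism graph per catalog drug.

    Propagation runs on ``network_for_propagation`` (typically confidence-
    filtered); graph edges come from ``full_ppi`` (unfiltered). Deterministic:
    identical inputs give identical node orderings.
    """
    config = config or PropagationConfig()
    graphs: dict[str, MechanismGraph] = {}
    for drug in catalog:
        try:
            if variant == "ppi_only":
                indirect: list[str] = []
            else:
                result = propagate_from_targets(network_for_propagation,
                                                drug.targets, config, pathways)
                indirect = select_indirect_targets(result, n=n_indirect)
            graphs[drug.drug_id] = build_mechanism_graph(
                drug, indirect, full_ppi, pathways, variant=variant)
        except ValueError as err:
            raise ValueError(f"drug {drug.drug_id}: {err}") from err
    return graphs


def write_graphs(graphs: dict[str, MechanismGraph], edges_path, nodes_path) -> None:
    """Export graphs as an edge-list TSV plus a node-attribute sidecar."""
    import pandas as pd

    edge_rows, node_rows = [], []
    for g in graphs.values():
        for u, v in g.gene_gene_edges:
            edge_rows.append((g.drug_id, u, v, "gene-gene"))
        for u, p in g.gene_pathway_edges:
            edge_rows.append((g.drug_id, u, p, "gene-pathway"))
        for node, kind in g.node_order():
            node_rows.append((g.drug_id, node, kind))
    pd.DataFrame(edge_rows, columns=["drug_id", "source", "target", "edge_kind"]).to_csv(
        edges_path, sep="\t", index=False)
    pd.DataFrame(node_rows, columns=["drug_id", "node_id", "kind"]).to_csv(
        nodes_path, sep="\t", index=False)
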