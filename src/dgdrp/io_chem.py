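"""Input readers, expression preprocessing and drug chemical featurization.

All cross-file joins are by gene symbol (case-sensitive). Drugs whose
targets are absent from the PPI network, or whose SMILES fail to parse,
are dropped with a logged count rather than raising, mirroring standard
practice when reconciling drug catalogs against interaction databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

FINGERPRINT_BITS = 128
FINGERPRINT_RADIUS = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x cell-lines expression matrix.

    Row order defines the canonical gene index used by every downstream
    mask and embedding.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # (g, c) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def cell_column(self, cell_id: str) -> np.ndarray:
        return self.values[:, self._cell_index[cell_id]]

    def cell_columns(self, cell_ids: list[str]) -> np.ndarray:
        """Return a (n_cells, g) array of expression rows for the given cells."""
        idx = [self._cell_index[c] for c in cell_ids]
        return self.values[:, idx].T

    def zscore(self) -> "ExpressionMatrix":
        """Per-gene z-scoring across cell lines (constant genes map to 0)."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(self.gene_ids, self.cell_ids, (self.values - mu) / sd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def write(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        # default float repr is the shortest round-trip form: bit-exact reload
        df.to_csv(path, sep="\t")


@dataclass
class PPINetwork:
    """Undirected weighted gene-gene interaction network.

    Edge confidence is on the STRING 0-1000 integer scale.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_gene(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def edges_with_scores(self):
        return ((u, v, d["score"]) for u, v, d in self.graph.edges(data=True))

    def subnetwork(self, min_score: int) -> "PPINetwork":
        """Edges at or above a confidence threshold; nodes are preserved."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_weighted_edges_from(
            ((u, v, s) for u, v, s in self.edges_with_scores() if s >= min_score),
            weight="score",
        )
        return PPINetwork(g)

    def write(self, path) -> None:
        rows = [(u, v, s) for u, v, s in self.edges_with_scores()]
        pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class PathwayCollection:
    """Mapping pathway_id -> (name, member gene set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def restricted_to(self, universe: set[str]) -> "PathwayCollection":
        """Intersect memberships with a gene universe, dropping emptied pathways."""
        kept = {}
        for pid, (name, members) in self.pathways.items():
            inter = members & universe
            if inter:
                kept[pid] = (name, frozenset(inter))
        return PathwayCollection(kept)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid, (name, members) in self.pathways.items():
                fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


@dataclass
class Drug:
    drug_id: str
    smiles: str | None
    targets: frozenset[str]
    fingerprint: np.ndarray  # (128,) uint8

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        if self.fingerprint.shape != (FINGERPRINT_BITS,):
            raise ValueError(
                f"drug {self.drug_id}: fingerprint length "
                f"{self.fingerprint.shape} != ({FINGERPRINT_BITS},)"
            )


@dataclass
class DrugCatalog:
    drugs: dict[str, Drug] = field(default_factory=dict)
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self):
        return iter(self.drugs.values())

    def __getitem__(self, drug_id: str) -> Drug:
        return self.drugs[drug_id]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.drugs

    @property
    def drug_ids(self) -> list[str]:
        return list(self.drugs)

    def write(self, path) -> None:
        rows = [
            (d.drug_id, d.smiles or "", ";".join(sorted(d.targets)),
             "".join(map(str, d.fingerprint)))
            for d in self
        ]
        pd.DataFrame(rows, columns=["drug_id", "smiles", "targets", "fingerprint"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ResponseTable:
    """(drug, cell line, response) triples; pairs are unique."""

    records: pd.DataFrame  # columns drug_id, cell_id, response

    def __post_init__(self) -> None:
        required = ["drug_id", "cell_id", "response"]
        if list(self.records.columns)[:3] != required:
            raise ValueError(f"response table must have columns {required}")
        dup = self.records.duplicated(subset=["drug_id", "cell_id"])
        if dup.any():
            pair = self.records.loc[dup.idxmax(), ["drug_id", "cell_id"]].tolist()
            raise ValueError(f"duplicate (drug, cell) pair: {pair}")
        if not np.all(np.isfinite(self.records["response"].to_numpy(dtype=float))):
            raise ValueError("non-finite response values")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.records["drug_id"].unique())

    def pairs_for_drugs(self, drug_ids) -> pd.DataFrame:
        wanted = set(drug_ids)
        return self.records[self.records["drug_id"].isin(wanted)].reset_index(drop=True)

    def validate_against(self, catalog: DrugCatalog, expression: ExpressionMatrix) -> None:
        missing_d = set(self.records["drug_id"]) - set(catalog.drug_ids)
        if missing_d:
            raise ValueError(f"response drugs missing from catalog: {sorted(missing_d)[:5]}")
        missing_c = set(self.records["cell_id"]) - set(expression.cell_ids)
        if missing_c:
            raise ValueError(f"response cells missing from expression: {sorted(missing_c)[:5]}")

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_expression(path, variance_top_n: int | None = None) -> ExpressionMatrix:
    """Read a genes-x-cells TSV; optionally keep the top-n most variable genes.

    Variance filtering keeps the ``variance_top_n`` genes of highest sample
    variance across cell lines while preserving the input gene order among
    survivors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    genes = df.index.astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()][0]
        raise ValueError(f"duplicate gene symbol in expression file: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna().to_numpy() & df.notna().to_numpy()
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        ) from None
    mat = ExpressionMatrix(list(genes), [str(c) for c in df.columns], values)
    if variance_top_n is not None and variance_top_n < mat.n_genes:
        var = mat.values.var(axis=1, ddof=1)
        # stable sort so ties keep input order; keep survivors in input order
        order = np.argsort(-var, kind="stable")[:variance_top_n]
        keep = np.sort(order)
        mat = ExpressionMatrix(
            [mat.gene_ids[i] for i in keep], mat.cell_ids, mat.values[keep]
        )
        logger.info("variance filter kept %d of %d genes", mat.n_genes, len(genes))
    return mat


def load_ppi(path, min_combined_score: int = 0) -> PPINetwork:
    """Read a STRING-style edge list (protein1, protein2, combined_score).

    Edges below ``min_combined_score`` are removed; duplicate orientations
    collapse to a single undirected edge keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"PPI file must have columns {sorted(required)}")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any():
        line = int(np.argmax(scores.isna().to_numpy())) + 2  # 1-based + header
        raise ValueError(f"malformed combined_score at line {line}")
    g = nx.Graph()
    for u, v, s in zip(df["protein1"], df["protein2"], scores):
        if pd.isna(u) or pd.isna(v):
            raise ValueError("malformed PPI row with missing protein id")
        u, v, s = str(u), str(v), int(s)
        if s < min_combined_score or u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], s)
        else:
            g.add_edge(u, v, score=s)
    return PPINetwork(g)


def load_pathways(path, universe: set[str] | None = None) -> PathwayCollection:
    """Read gene sets in GMT format (id, description, members...)."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            pid, name, members = fields[0], fields[1], frozenset(fields[2:])
            if universe is not None:
                members = members & universe
            if members:
                pathways[pid] = (name, frozenset(members))
    return PathwayCollection(pathways)


def load_drugs(path, ppi: PPINetwork | None = None,
               compute_fingerprints: bool = True) -> DrugCatalog:
    """Read a drug catalog TSV (drug_id, smiles, targets; optional fingerprint).

    Drugs with no parseable SMILES (when fingerprints must be computed), no
    targets, or no target on the PPI network are dropped; the count is logged
    and recorded on the catalog.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"drug_id", "smiles", "targets"}.issubset(df.columns):
        raise ValueError("drug file must have columns drug_id, smiles, targets")
    catalog = DrugCatalog()
    dropped = 0
    for _, row in df.iterrows():
        drug_id = row["drug_id"]
        smiles = row["smiles"] or None
        targets = frozenset(t for t in row["targets"].split(";") if t)
        if ppi is not None:
            targets = frozenset(t for t in targets if ppi.has_gene(t))
        if not targets:
            dropped += 1
            continue
        if "fingerprint" in df.columns and row.get("fingerprint"):
            fp = np.array([int(b) for b in row["fingerprint"]], dtype=np.uint8)
        elif compute_fingerprints:
            if smiles is None:
                dropped += 1
                continue
            try:
                smiles = canonicalize_smiles(smiles, drug_id=drug_id)
                fp = morgan_fingerprint(smiles)
            except ValueError:
                dropped += 1
                continue
        else:
            dropped += 1
            continue
        catalog.drugs[drug_id] = Drug(drug_id, smiles, targets, fp)
    catalog.n_dropped = dropped
    if dropped:
        logger.info("dropped %d of %d drugs lacking SMILES or on-network targets",
                    dropped, len(df))
    return catalog


def load_responses(path) -> ResponseTable:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "cell_id": str},
                     float_precision="round_trip")
    df["response"] = pd.to_numeric(df["response"])
    return ResponseTable(df[["drug_id", "cell_id", "response"]])


# ---------------------------------------------------------------------------
# Chemistry
# ---------------------------------------------------------------------------

def canonicalize_smiles(smiles: str, drug_id: str | None = None) -> str:
    """Deterministic canonical SMILES; idempotent."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        who = f" for drug {drug_id!r}" if drug_id else ""
        raise ValueError(f"unparseable SMILES{who}: {smiles!r}")
    return Chem.MolToSmiles(mol)


def morgan_fingerprint(smiles: str, n_bits: int = FINGERPRINT_BITS,
                       radius: int = FINGERPRINT_RADIUS) -> np.ndarray:
    """Morgan (ECFP-style) binary fingerprint, default 128 bits, radius 2."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")
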