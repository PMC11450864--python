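"""The end-to-end drug-response model with drug-specific gene selection.

For a drug *i* and cell line *j* the forward pass is:

1. Encode the drug's mechanism graph with a 3-layer graph attention
   network interleaved with top-k pooling and a feature-skip mean
   readout, using the cell line's expression values as gene-node
   features (pathway nodes get feature 0): the mechanism embedding
   ``Z_T = GNN(G_i, X_j)``.
2. Embed every gene of the universe: a learned per-gene identity embedding
   concatenated with the gene's scalar expression, through a shared MLP,
   giving ``Z_G`` (g x d).
3. Score genes by the dot product ``S = Z_G . Z_T`` and build a hard top-k
   mask (k = 100 by default) over the gene universe.
4. Apply the mask to the expression vector, encode the masked profile and
   the drug's 128-bit Morgan fingerprint with MLPs, concatenate
   ``[Z_D, Z_C, Z_T]`` and regress the response with a 3-layer predictor.

The mask is recomputed for every (drug, cell line) pair, so the cell-line
representation adapts to the drug. Hard selection is non-differentiable;
by default a straight-through estimator passes the masked-expression
gradient back to the similarity scores so the gene encoder keeps learning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, concat
from .mechanism_graph import MechanismGraph
from .nn import MLP, GATLayer, Linear, Module, TopKPool, topk_gate

logger = logging.getLogger(__name__)

DEFAULT_K_SELECT = 100

_KIND_BITS = {"direct": (1.0, 0.0), "indirect": (0.0, 1.0), "pathway": (0.0, 0.0)}


@dataclass
class ModelConfig:
    embed_dim: int = 32
    k_select: int = DEFAULT_K_SELECT
    gnn_layers: int = 3
    pooling_ratio: float = 0.5
    gating: str = "straight_through"  # {"hard", "straight_through", "soft_topk"}
    gene_id_dim: int = 8
    gene_hidden: int = 32
    cell_hidden: tuple[int, ...] = (128,)
    drug_hidden: tuple[int, ...] = (64,)
    predictor_hidden: tuple[int, ...] = (64, 32)
    dropout: float = 0.0
    cosine_similarity: bool = False

    def __post_init__(self) -> None:
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if self.k_select <= 0:
            raise ValueError("k_select must be positive")
        if self.gating not in ("hard", "straight_through", "soft_topk"):
            raise ValueError(f"unknown gating {self.gating!r}")


class GraphTensors:
    """Numpy views of a mechanism graph, ready for the encoder.

    ``gene_idx`` maps each node to its row in the expression universe
    (-1 for pathway nodes and genes missing from the universe, which get
    feature 0); ``adj`` is the dense boolean adjacency with self-loops.
    """

    def __init__(self, graph: MechanismGraph, gene_index: dict[str, int]):
        if graph.n_nodes == 0:
            raise ValueError(f"drug {graph.drug_id}: empty mechanism graph")
        order = graph.node_order()
        self.drug_id = graph.drug_id
        self.n = len(order)
        pos = {node: i for i, (node, _) in enumerate(order)}
        self.gene_idx = np.full(self.n, -1, dtype=int)
        self.kind_bits = np.zeros((self.n, 2))
        missing = 0
        for i, (node, kind) in enumerate(order):
            self.kind_bits[i] = _KIND_BITS[kind]
            if kind != "pathway":
                gi = gene_index.get(node, -1)
                if gi < 0:
                    missing += 1
                self.gene_idx[i] = gi
        if missing:
            logger.info("drug %s: %d graph genes missing from expression universe",
                        graph.drug_id, missing)
        adj = np.eye(self.n, dtype=bool)
        for u, v in graph.gene_gene_edges:
            adj[pos[u], pos[v]] = adj[pos[v], pos[u]] = True
        for u, p in graph.gene_pathway_edges:
            adj[pos[u], pos[p]] = adj[pos[p], pos[u]] = True
        self.adj = adj

    def node_features(self, X: np.ndarray) -> np.ndarray:
        """(B, n, 3) features: scalar expression plus a 2-bit kind one-hot."""
        B = X.shape[0]
        vals = np.zeros((B, self.n))
        on = self.gene_idx >= 0
        vals[:, on] = X[:, self.gene_idx[on]]
        kind = np.broadcast_to(self.kind_bits, (B, self.n, 2))
        return np.concatenate([vals[..., None], kind], axis=-1)


class MechanismEncoder(Module):
    """GAT + top-k pooling stack with a feature-skip mean readout.

    The readout is the mean over surviving nodes of the final attention
    layer plus a learned linear lift of the mean gene-node expression.
    The skip term matters: it exposes the mechanism genes' expression to
    the predictor (and to the similarity scores) from the first step,
    instead of leaving it attenuated behind three attention layers whose
    gradients are still asleep at initialization.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d = config.embed_dim
        self.lift = Linear(3, d, rng)
        self.gat_layers = [GATLayer(d, d, rng) for _ in range(config.gnn_layers)]
        self.pools = [TopKPool(d, rng, config.pooling_ratio)
                      for _ in range(config.gnn_layers)]
        self.skip = Linear(1, d, rng)

    def __call__(self, gt: GraphTensors, X: np.ndarray) -> Tensor:
        feats = gt.node_features(X)
        h = Tensor(feats) @ self.lift.W + self.lift.b
        adj = gt.adj
        for gat, pool in zip(self.gat_layers, self.pools):
            h = gat(h, adj)
            h, adj, _ = pool(h, adj)
        gene_nodes = gt.gene_idx >= 0
        if gene_nodes.any():
            xbar = feats[:, gene_nodes, 0].mean(axis=1, keepdims=True)
        else:
            xbar = np.zeros((feats.shape[0], 1))
        return h.mean(axis=1) + self.skip(Tensor(xbar))  # (B, d)


class GeneEncoder(Module):
    """Row-wise gene embedding: MLP over (identity embedding, expression).

    The first layer is split so the identity part is computed once per
    batch: h = relu(E @ W_id + x * w_x + b), then a linear map to d.
    """

    def __init__(self, n_genes: int, config: ModelConfig, rng: np.random.Generator):
        e, h, d = config.gene_id_dim, config.gene_hidden, config.embed_dim
        # unit-scale identity embeddings: comparable in magnitude to the
        # expression term, so gene identity (not per-cell expression noise)
        # anchors the similarity ranking from the start
        self.id_embedding = Tensor(rng.normal(0, 1.0, size=(n_genes, e)),
                                   requires_grad=True)
        self.W_id = Tensor(rng.uniform(-1, 1, (e, h)) * np.sqrt(6 / (e + 1 + h)),
                           requires_grad=True)
        # the expression channel starts at 1/10 of the identity scale: the
        # initial similarity ranking is then stable across cell lines
        # (identity-anchored) instead of churning with per-cell expression;
        # the channel grows during training where expression proves useful
        self.w_x = Tensor(rng.uniform(-1, 1, (1, h)) * np.sqrt(6 / (e + 1 + h))
                          * 0.1, requires_grad=True)
        self.b = Tensor(np.zeros(h), requires_grad=True)
        self.out = Linear(h, d, rng)

    def __call__(self, X: Tensor) -> Tensor:
        # X: (B, g) -> (B, g, d)
        B, g = X.shape
        id_part = self.id_embedding @ self.W_id              # (g, h)
        x_part = X.reshape(B, g, 1) @ self.w_x               # (B, g, h)
        h = (x_part + id_part + self.b).relu()
        return self.out(h)


class DGDRPModel(Module):
    """Mechanism-guided gene selection + response regression."""

    def __init__(self, gene_ids: list[str], config: ModelConfig | None = None,
                 seed: int = 0):
        self.config = config or ModelConfig()
        self.gene_ids = list(gene_ids)
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        g = len(self.gene_ids)
        if self.config.k_select > g:
            raise ValueError(f"k_select={self.config.k_select} exceeds "
                             f"gene universe size {g}")
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = self.config.embed_dim
        self.mechanism_encoder = MechanismEncoder(self.config, rng)
        self.gene_encoder = GeneEncoder(g, self.config, rng)
        self.cell_encoder = MLP([g, *self.config.cell_hidden, d], rng)
        self.drug_encoder = MLP([128, *self.config.drug_hidden, d], rng)
        self.predictor = MLP([3 * d, *self.config.predictor_hidden, 1], rng)
        self.training = False
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- pieces, exposed for inspection and tests ---------------------------
    def graph_tensors(self, graph: MechanismGraph) -> GraphTensors:
        return GraphTensors(graph, self.gene_index)

    def encode_mechanism(self, gt: GraphTensors, X: np.ndarray) -> Tensor:
        return self.mechanism_encoder(gt, np.atleast_2d(X))

    def encode_genes(self, X: np.ndarray) -> Tensor:
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.gene_ids):
            raise ValueError(f"expression length {X.shape[1]} != gene universe "
                             f"{len(self.gene_ids)}")
        return self.gene_encoder(Tensor(X))

    def similarity_scores(self, Z_G: Tensor, Z_T: Tensor) -> Tensor:
        B, g, d = Z_G.shape
        if Z_T.shape != (B, d):
            raise ValueError(f"mechanism embedding shape {Z_T.shape} does not "
                             f"match gene embeddings {(B, d)}")
        if self.config.cosine_similarity:
            gn = ((Z_G * Z_G).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
            tn = ((Z_T * Z_T).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
            Z_G = Z_G / gn
            Z_T = Z_T / tn
        return (Z_G @ Z_T.reshape(B, d, 1)).reshape(B, g)

    def encode_cell(self, masked: Tensor) -> Tensor:
        # dropout-style compensation: only k of g entries are nonzero, so
        # rescale to keep the encoder's activation scale independent of k
        scale = float(len(self.gene_ids)) / self.config.k_select
        return self.cell_encoder(masked * scale)

    def encode_drug(self, fingerprint: np.ndarray) -> Tensor:
        fp = np.atleast_2d(np.asarray(fingerprint, dtype=float))
        if fp.shape[1] != 128:
            raise ValueError(f"fingerprint length {fp.shape[1]} != 128")
        return self.drug_encoder(Tensor(fp))  # (1, d)

    # -- full forward --------------------------------------------------------
    def forward(self, gt: GraphTensors, fingerprint: np.ndarray,
                X: np.ndarray, return_mask: bool = False):
        """Predict responses for one drug against a batch of cell lines.

        ``X`` is (B, g) expression in universe order; returns a (B,) tensor
        of predictions (and the (B, g) integer mask when requested).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = X.shape[0]
        Z_T = self.encode_mechanism(gt, X)                     # (B, d)
        Z_G = self.encode_genes(X)                             # (B, g, d)
        S = self.similarity_scores(Z_G, Z_T)                   # (B, g)
        masked, mask = topk_gate(Tensor(X), S, self.config.k_select,
                                 mode=self.config.gating)
        Z_C = self.encode_cell(masked)                         # (B, d)
        z_d = self.encode_drug(fingerprint)                    # (1, d)
        Z_D = Tensor(np.ones((B, 1))) @ z_d                    # broadcast to (B, d)
        h = concat([Z_D, Z_C, Z_T], axis=-1)
        if self.training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            drop = self._dropout_rng.random(h.shape) < keep
            h = h * Tensor(drop / keep)
        y = self.predictor(h).reshape(B)
        assert int(mask.sum(axis=1).min()) == self.config.k_select  # mask contract
        if return_mask:
            return y, mask
        return y

    __call__ = forward

    # -- persistence ---------------------------------------------------------
    def gene_universe_hash(self) -> str:
        return hashlib.sha256("\n".join(self.gene_ids).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        state = self.state_dict()
        meta = {"config": asdict(self.config), "seed": self.seed,
                "gene_ids": self.gene_ids,
                "gene_universe_hash": self.gene_universe_hash()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "DGDRPModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = meta["config"]
            for key in ("cell_hidden", "drug_hidden", "predictor_hidden"):
                cfg[key] = tuple(cfg[key])
            model = cls(meta["gene_ids"], ModelConfig(**cfg), seed=meta["seed"])
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


class AllGenesBaseline(Module):
    """Same encoders and predictor, no gene selection and no mechanism graph.

    The comparison point for the selection method: the full expression
    profile goes straight into the cell encoder and the predictor sees
    ``[Z_D, Z_C]`` only.
    """

    def __init__(self, gene_ids: list[str], config: ModelConfig | None = None,
                 seed: int = 0):
        self.config = config or ModelConfig()
        self.gene_ids = list(gene_ids)
        self.seed = seed
        rng = np.random.default_rng(seed)
        g, d = len(self.gene_ids), self.config.embed_dim
        self.cell_encoder = MLP([g, *self.config.cell_hidden, d], rng)
        self.drug_encoder = MLP([128, *self.config.drug_hidden, d], rng)
        self.predictor = MLP([2 * d, *self.config.predictor_hidden, 1], rng)
        self.training = False

    def forward(self, gt, fingerprint: np.ndarray, X: np.ndarray,
                return_mask: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        B = X.shape[0]
        Z_C = self.cell_encoder(Tensor(X))
        fp = np.atleast_2d(np.asarray(fingerprint, dtype=float))
        z_d = self.drug_encoder(Tensor(fp))
        Z_D = Tensor(np.ones((B, 1))) @ z_d
        y = self.predictor(concat([Z_D, Z_C], axis=-1)).reshape(B)
        if return_mask:
            return y, np.ones((B, len(self.gene_ids)), dtype=int)
        return y

    __call__ = forward

    def graph_tensors(self, graph) -> None:  # baseline ignores the graph
        return None
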