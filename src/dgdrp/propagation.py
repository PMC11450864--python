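"""Network propagation from drug targets: random walk with restart (RWR).

Genes are ranked by the stationary distribution of a restarting random walk
seeded at a drug's direct targets,

    p_{t+1} = (1 - alpha) W p_t + alpha p_0,

where W is the column-normalized (weighted) adjacency matrix and alpha the
restart probability. The fixed point solves (I - (1-alpha) W) p = alpha p_0.
An optional one-round pathway reinforcement boosts the restart mass of genes
belonging to pathways over-represented among the top propagated genes, in
the spirit of pathway-enhanced propagation schemes.

Zero-degree (dangling) columns of W are left all-zero: mass walking into an
isolated node would have nowhere to go, so under this policy it simply
re-enters through the restart term. Consequently sum(p*) = 1 holds exactly
only when every seed-reachable node has neighbors; on connected graphs it
always holds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import hypergeom

from .io_chem import PPINetwork, PathwayCollection

logger = logging.getLogger(__name__)

DEFAULT_N_INDIRECT = 20


@dataclass
class PropagationConfig:
    alpha: float = 0.2
    tol: float = 1e-8
    max_iter: int = 1000
    reinforcement: str = "off"  # {"off", "one_round"}
    boost_factor: float = 2.0
    enrich_p_cutoff: float = 0.05
    enrich_top_q: int = 100  # top propagated genes fed to the enrichment test

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.reinforcement not in ("off", "one_round"):
            raise ValueError(f"unknown reinforcement mode {self.reinforcement!r}")
        if self.boost_factor < 1:
            raise ValueError("boost_factor must be >= 1")


@dataclass
class PropagationResult:
    gene_ids: list[str]
    scores: np.ndarray
    seeds: frozenset[str]
    iterations_used: int
    converged: bool = True
    p0: np.ndarray | None = field(default=None, repr=False)

    def score_of(self, gene: str) -> float:
        return float(self.scores[self.gene_ids.index(gene)])

    def top_genes(self, n: int) -> list[str]:
        order = np.argsort(-self.scores, kind="stable")[:n]
        return [self.gene_ids[i] for i in order]


def column_normalize(network: PPINetwork, weighted: bool = True):
    """Column-normalized sparse adjacency of the network.

    Returns ``(W, gene_ids)`` where ``W`` is CSR with each nonzero-degree
    column summing to 1; zero-degree columns stay all-zero.
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("cannot normalize an empty network")
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, s in network.edges_with_scores():
        w = float(s) if weighted else 1.0
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    n = len(nodes)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    colsum = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    W = A @ sp.diags(inv)
    return W.tocsr(), nodes


def rwr_propagate(W, gene_ids: list[str], seeds,
                  config: PropagationConfig | None = None,
                  p0: np.ndarray | None = None) -> PropagationResult:
    """Iterate the restarting random walk to its fixed point.

    ``p0`` defaults to uniform mass over the seed genes. Iteration stops when
    the L1 change drops below ``config.tol`` or at ``config.max_iter`` (the
    latter flags ``converged=False`` and warns).
    """
    config = config or PropagationConfig()
    seeds = frozenset(seeds)
    index = {g: i for i, g in enumerate(gene_ids)}
    on_network = [s for s in seeds if s in index]
    if not on_network:
        raise ValueError(f"no seed gene is on the network: {sorted(seeds)}")
    if p0 is None:
        p0 = np.zeros(len(gene_ids))
        p0[[index[s] for s in on_network]] = 1.0 / len(on_network)
    else:
        p0 = np.asarray(p0, dtype=float)
        p0 = p0 / p0.sum()

    alpha = config.alpha
    p = p0.copy()
    converged = False
    it = 0
    # contraction bound: ||p_t - p*||_1 <= (1-a)/a * ||p_{t+1} - p_t||_1,
    # so scale the step-difference test to make tol a bound on the true
    # distance to the fixed point
    safety = (1 - alpha) / alpha if alpha < 1 else 1.0
    for it in range(1, config.max_iter + 1):
        p_next = (1 - alpha) * (W @ p) + alpha * p0
        if np.abs(p_next - p).sum() * max(safety, 1.0) < config.tol:
            p = p_next
            converged = True
            break
        p = p_next
    if not converged:
        warnings.warn(f"RWR did not converge within {config.max_iter} iterations",
                      RuntimeWarning, stacklevel=2)
    return PropagationResult(gene_ids, p, seeds, it, converged, p0=p0)


def propagate_from_targets(network: PPINetwork, targets,
                           config: PropagationConfig | None = None,
                           pathways: PathwayCollection | None = None,
                           ) -> PropagationResult:
    """Full ranking pipeline for one drug: normalize, propagate, optionally
    reinforce with pathway enrichment."""
    config = config or PropagationConfig()
    W, gene_ids = column_normalize(network)
    result = rwr_propagate(W, gene_ids, targets, config)
    if config.reinforcement == "one_round":
        result = reinforce_with_pathways(result, pathways, config, W=W)
    return result


def reinforce_with_pathways(result: PropagationResult,
                            pathways: PathwayCollection | None,
                            config: PropagationConfig,
                            W=None) -> PropagationResult:
    """One round of pathway-knowledge reinforcement.

    The top ``enrich_top_q`` propagated genes are tested for over-representation
    in each pathway (hypergeometric upper tail, network genes as background,
    Benjamini-Hochberg adjusted). Genes belonging to any pathway significant at
    ``enrich_p_cutoff`` get their restart mass multiplied by ``boost_factor``;
    the restart vector is renormalized and the walk re-run once.
    """
    from statsmodels.stats.multitest import multipletests

    if pathways is None or len(pathways) == 0:
        warnings.warn("pathway reinforcement requested with no pathways; "
                      "returning propagation result unchanged", RuntimeWarning,
                      stacklevel=2)
        return result
    if W is None:
        raise ValueError("reinforce_with_pathways needs the transition matrix W")

    background = set(result.gene_ids)
    top = set(result.top_genes(config.enrich_top_q))
    pids, pvals, member_sets = [], [], []
    for pid, (_, members) in pathways:
        members = frozenset(members) & background
        if not members:
            continue
        overlap = len(top & members)
        # P(X >= overlap), X ~ Hypergeom(N=|bg|, K=|pathway|, n=|top|)
        p = float(hypergeom.sf(overlap - 1, len(background), len(members), len(top)))
        pids.append(pid)
        pvals.append(p)
        member_sets.append(members)
    if not pids:
        return result
    adj = multipletests(pvals, method="fdr_bh")[1]
    boosted_genes: set[str] = set()
    for p_adj, members in zip(adj, member_sets):
        if p_adj < config.enrich_p_cutoff:
            boosted_genes |= members
    if not boosted_genes or config.boost_factor == 1.0:
        return result

    index = {g: i for i, g in enumerate(result.gene_ids)}
    p0 = result.p0.copy()
    for g in boosted_genes:
        p0[index[g]] *= config.boost_factor
    # genes outside the original seed set get a share of restart mass too,
    # proportional to their propagated score, so pathway membership can pull
    # in genes beyond the direct targets
    boost_idx = [index[g] for g in boosted_genes]
    p0[boost_idx] += result.scores[boost_idx] * (config.boost_factor - 1.0)
    p0 /= p0.sum()
    rerun = rwr_propagate(W, result.gene_ids, result.seeds, config, p0=p0)
    return rerun


def select_indirect_targets(result: PropagationResult, n: int = DEFAULT_N_INDIRECT,
                            exclude_seeds: bool = True) -> list[str]:
    """The n highest-scoring genes; ties broken by ascending gene index.

    Direct targets are excluded by default: they trivially top the ranking
    and the mechanism graph treats direct and indirect target sets as
    disjoint.
    """
    order = np.argsort(-result.scores, kind="stable")
    picked: list[str] = []
    for i in order:
        g = result.gene_ids[i]
        if exclude_seeds and g in result.seeds:
            continue
        picked.append(g)
        if len(picked) == n:
            break
    return picked
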