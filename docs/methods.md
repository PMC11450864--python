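# Methods

## The model

`dgdrp` predicts the response (an IC50-scale value) of a cell line to a
drug while *selecting, per drug and cell line, the genes used for the
prediction*. The premise is mechanistic: a drug perturbs its target
proteins, the perturbation spreads through protein-protein interactions,
and the genes most affected carry the signal that determines response.
The pipeline therefore ranks genes twice:

1. **Knowledge-guided ranking (propagation).** A random walk with restart
   on the interaction network, seeded uniformly at the drug's direct
   targets:

       p_{t+1} = (1 - α) W p_t + α p_0,

   with W the column-normalized weighted adjacency and α the restart
   probability. The fixed point solves (I − (1−α)W) p = α p_0 and scores
   every gene's network proximity to the targets. The 20 top-scoring
   non-target genes are the drug's *indirect targets*. An optional
   one-round pathway reinforcement (off by default, see below) boosts the
   restart mass of genes in pathways over-represented among the top
   propagated genes.

2. **Learned re-ranking (embedding similarity).** A heterogeneous
   *mechanism graph* per drug joins direct targets, indirect targets, all
   interaction edges among them (no confidence cutoff), and the pathways
   containing indirect targets (membership edges from indirect targets
   only). A 3-layer graph attention network with top-k pooling (ratio
   0.5) and a feature-skip mean readout encodes the graph into a
   mechanism embedding Z_T, using the cell line's expression as
   gene-node features and 0 for pathway nodes. Every gene of the universe is separately embedded
   (Z_G, one d-vector per gene), genes are scored by the dot product
   S = Z_G · Z_T, and the top k = 100 scores define a binary mask. The
   masked expression profile, the drug's 128-bit Morgan fingerprint
   (radius 2) and Z_T are encoded by MLPs, concatenated, and regressed to
   the response by a 3-layer predictor. Training minimizes MSE with Adam
   at learning rate 1e-4.

## Design choices where the architecture was open

- **Gene encoder.** The mapping from the expression vector to per-gene
  embeddings is implemented as a learned per-gene identity embedding
  (8-dim) concatenated with the gene's scalar expression, passed through
  a shared MLP. This keeps the parameter count O(g·d) and makes rows
  expression-dependent; two cell lines differing at one gene differ in
  exactly that embedding row.
- **Gating.** Hard top-k masking is non-differentiable. The default is a
  straight-through estimator: the forward pass uses the hard mask, the
  backward pass hands the masked-expression gradient to the similarity
  scores, so the gene encoder keeps receiving signal. `hard` (gradients
  reach the selection only through the mechanism-embedding path) and
  `soft_topk` (selected entries weighted by softmax-normalized scores)
  are selectable.
- **Heterogeneous nodes.** Node kinds (direct / indirect / pathway) enter
  as a 2-bit indicator appended to the scalar feature before the linear
  lift; the attention layers themselves are untyped.
- **Ties.** All top-k selections (masking, pooling, indirect-target
  choice) break ties toward the lower canonical gene index, making every
  mask and graph bit-reproducible.
- **Dangling nodes.** Zero-degree columns of W stay all-zero; walk mass
  entering them returns through the restart term. On connected graphs
  Σp* = 1 exactly (to solver tolerance).
- **Pathway reinforcement.** The published description of the
  pathway-enhanced propagation step delegates its exact update to an
  earlier algorithm and is under-specified here; this package implements
  a documented interpretation: hypergeometric over-representation of the
  top-100 propagated genes per pathway (network genes as background,
  Benjamini-Hochberg adjusted at 0.05), then enriched-pathway members
  receive extra restart mass — their p_0 entries are multiplied by the
  boost factor *and* incremented proportionally to their current
  propagation score (a pure multiplicative boost would be a no-op for
  non-seed genes, whose restart mass is zero) — and the walk is re-run
  once. Because this is an interpretation, it defaults to **off**; the
  base pipeline is plain restart-walk ranking.
- **Readout.** The mechanism embedding is the mean over surviving nodes
  of the final attention layer **plus** a learned linear lift of the
  mean gene-node expression (a feature skip). Without the skip the
  graph path has vanishing gradients at initialization and the
  mechanism signal never reaches the predictor at small learning rates.
- **Initialization balance.** Gene identity embeddings start at unit
  scale and the gene encoder's expression channel at a tenth of it, so
  the initial similarity ranking is anchored by gene identity (stable
  across cell lines) rather than churning with per-cell expression; the
  expression channel grows in training where it earns its keep.
- **Mask-scale compensation.** The cell encoder rescales the masked
  profile by g/k (as dropout rescales kept units), keeping its
  activation scale independent of how many genes are selected.
- **RWR convergence.** The iteration stops when the L1 step difference,
  scaled by the contraction factor (1−α)/α, falls below the tolerance —
  so the tolerance bounds the distance to the fixed point itself, not
  just the last step.
- **Metrics.** RMSE, Pearson and Spearman correlations are implemented
  directly (Spearman as Pearson of average ranks) and verified against
  scipy to 1e-12 in the tests.

## The neural stack

The model is built on a compact reverse-mode automatic differentiation
engine over dense numpy arrays (`dgdrp.autograd`), with the layers it
needs in `dgdrp.nn`: linear/MLP stacks, a dense single-head graph
attention layer, top-k pooling, the straight-through top-k gate, and
Adam. Mechanism graphs have tens of nodes and gene universes are in the
thousands, so dense batched linear algebra is the right tool; every
operation's gradient is checked against central finite differences in
the test suite.

## The synthetic benchmark

All tests run on generated data with known ground truth; the generator
(`dgdrp.synthetic_data`) emulates the statistical structure the method
assumes:

- **Network**: connected preferential-attachment (scale-free) graph,
  integer confidences uniform on [400, 1000] so score filtering is
  meaningful.
- **Pathways**: overlapping breadth-first balls (10-50 genes) around
  sampled centers, so membership correlates with network proximity; one
  extra pathway per drug is planted at its first target, giving
  enrichment recovery a known answer.
- **Drugs**: 1-3 network targets, a fixed random 128-bit fingerprint
  (the chemistry path is exercised separately on real SMILES), and a
  planted mechanism: the top-50 restart-walk neighborhood of the
  targets.
- **Expression**: per-gene baselines plus rank-5 cell-line factors plus
  independent Gaussian noise (sd 0.5), with lognormal per-gene loading
  scales so variance filtering is meaningful. Factor loadings are
  smoothed along network edges (3 neighbor-averaging rounds, mixing 0.7)
  before scaling: interacting genes are co-expressed, as in real
  transcriptomes. Without this coupling, network-neighborhood genes
  would be statistically independent of mechanism-node expression and
  no embedding-similarity method could find them even in principle.
- **Responses**: y(i,j) = Σ_planted β·x + γ·fingerprint + ε with
  ε ~ N(0, 0.3). Coefficients are sign-consistent, β = |N(0, 1)|/√m:
  mechanism-gene activity pushes the response in one direction, as when
  target-pathway activity drives sensitivity. With sign-random
  coefficients the planted contribution of an *unseen* drug would be
  unpredictable in principle and a drug-split benchmark could not
  separate mechanism-aware from mechanism-blind models.

What the generator does **not** emulate: real IC50 distributions,
dose-response curve fitting noise, batch effects, mutation/CNV
covariates, or curated pathway hierarchies. Passing the recovery tests
shows the method recovers planted mechanism signal under the generator's
assumptions, not that it reproduces benchmark figures on public
drug-response databases.

## Evaluation protocol

The data split is by **drug**: all pairs of a test drug are held out
together, so metrics measure generalization to unseen drugs — the regime
where gene selection can matter, since per-drug memorization is
impossible. Cross-validation shuffles drugs with the seed into
near-even folds; within a training fold, 10% of drugs (at least one)
form the validation set for early stopping (patience 5 on validation
MSE, best state restored).

At the benchmark scale used here (30 drugs, 120 cell lines, 1000 genes)
the drug-level validation set is only ~3 drugs and its MSE is too noisy
a stopping signal, so the synthetic recovery evaluation trains for a
fixed 90 epochs (batch size 32, one drug per batch) and restores the
best-validation parameter state; patience-based stopping remains the
default in the training API and CLI. The recovery evaluation uses one
drug split per seed (5 test drugs) across 3 seeds rather than full
5-fold cross-validation per seed, and trains in float32; problem sizes
were chosen so the full suite runs on a laptop-class single core.

## What the benchmark shows — and what it does not

Linear probes (recomputed by `scripts/acceptance.py` on every run) put
the pieces in proportion. On unseen drugs, ridge regression on the full
expression profile plus the fingerprint substantially outperforms the
same regression on the mechanism-graph summary (mean mechanism-gene
expression plus fingerprint), while an oracle probe that averages each
drug's true planted genes outperforms both — so mechanism knowledge is
worth a lot, but only at finer granularity than a 20-gene neighborhood
mean.

Two generator properties interact to make the mechanism-blind baseline
strong here: sign-consistent planted effects and network-correlated
co-expression together create a drug-agnostic "hub module activity"
signal that a model reading all genes exploits fully. The masked model
must first *learn* which genes to read, and the straight-through
gradient of a never-selected gene passes through untrained encoder
weights — noise — so selection converges far more slowly than
prediction. At this desk scale (≈ 3000 training pairs, learning rate
1e-4) the trained selector narrows but does not close the gap to the
all-genes baseline, and its selected sets recover planted genes only
weakly; the test suite states both comparisons as assertions and
reports them as they come out. On the published task's scale (~170k
pairs, 10,000 genes) the corresponding comparison is reported with the
opposite direction; the desk-scale benchmark should therefore be read
as a mechanical verification of the pipeline's contracts, not as a
reproduction of the selection advantage.

## Known limitations

- The straight-through selection gradient for a never-selected gene
  estimates its usefulness through untrained encoder weights, so the
  exploration signal for the selection mask is noisy at small sample
  sizes; selection stabilizes much more slowly than prediction accuracy.
- The mechanism embedding uses expression values as node features
  without gene-identity features (as specified for the published
  architecture), so drug discrimination rests on graph topology and
  expression patterns alone.
- Propagation treats the interaction network as undirected and
  confidence-weighted; no edge directionality or sign.
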