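"""Drug-split cross-validation, training with early stopping, and metrics.

The data split is at the drug level ("drug split"): all response pairs of a
test drug are held out together, so evaluation measures generalization to
drugs the model has never seen. Within each training fold a further
drug-level slice (10% of training drugs by default) serves as the
validation set for early stopping.

Metrics are root-mean-square error, Pearson correlation and Spearman
correlation (Pearson of average ranks), implemented directly and checked
against independent references in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dgdrp_model import AllGenesBaseline, DGDRPModel, ModelConfig
from .io_chem import DrugCatalog, ExpressionMatrix, ResponseTable
from .mechanism_graph import batch_build
from .nn import Adam
from .propagation import PropagationConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(y, yhat) -> float:
    y, yhat = _aligned(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(y, yhat) -> float:
    """Pearson product-moment correlation."""
    y, yhat = _aligned(y, yhat)
    if len(y) < 2:
        raise ValueError("correlation needs at least 2 samples")
    yc, pc = y - y.mean(), yhat - yhat.mean()
    denom = np.sqrt((yc ** 2).sum() * (pc ** 2).sum())
    if denom == 0:
        warnings.warn("zero-variance input to pcc; returning nan",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((yc * pc).sum() / denom)


def scc(y, yhat) -> float:
    """Spearman correlation: Pearson of average-rank vectors."""
    y, yhat = _aligned(y, yhat)
    if len(y) < 2:
        raise ValueError("correlation needs at least 2 samples")
    return pcc(rankdata(y), rankdata(yhat))


def _aligned(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


@dataclass
class MetricReport:
    rmse: float
    pcc: float
    scc: float
    n: int
    per_fold: list[dict] = field(default_factory=list)
    sd: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold_of: dict[str, int]
    n_folds: int

    def drugs_in_fold(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.fold_of.items() if f == fold)

    def train_drugs(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.fold_of.items() if f != fold)


def drug_split_folds(table: ResponseTable, n_folds: int = 5,
                     seed: int = 0) -> FoldAssignment:
    """Shuffle drugs with the seed and partition them near-evenly."""
    drugs = table.drug_ids
    if len(drugs) < n_folds:
        raise ValueError(f"{len(drugs)} drugs cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(drugs))
    fold_of = {d: i % n_folds for i, d in enumerate(order)}
    return FoldAssignment(fold_of, n_folds)


# ---------------------------------------------------------------------------
# Training data container
# ---------------------------------------------------------------------------

@dataclass
class TrainingData:
    """Expression, fingerprints, mechanism graphs and response pairs,
    pre-indexed for batched training."""

    gene_ids: list[str]
    X_cells: np.ndarray               # (n_cells, g)
    cell_index: dict[str, int]
    fingerprints: dict[str, np.ndarray]
    graphs: dict[str, object]         # drug_id -> MechanismGraph
    responses: ResponseTable

    @classmethod
    def from_inputs(cls, expression: ExpressionMatrix, catalog: DrugCatalog,
                    responses: ResponseTable, ppi, pathways,
                    propagation_min_score: int = 800,
                    propagation_config: PropagationConfig | None = None,
                    n_indirect: int = 20, variant: str = "full",
                    ) -> "TrainingData":
        responses.validate_against(catalog, expression)
        prop_net = ppi.subnetwork(propagation_min_score)
        graphs = batch_build(catalog, prop_net, ppi, pathways,
                             config=propagation_config,
                             n_indirect=n_indirect, variant=variant)
        return cls(
            gene_ids=list(expression.gene_ids),
            X_cells=expression.values.T.copy(),
            cell_index={c: i for i, c in enumerate(expression.cell_ids)},
            fingerprints={d.drug_id: d.fingerprint.astype(float) for d in catalog},
            graphs=graphs,
            responses=responses,
        )

    def pairs_by_drug(self, drug_ids) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """drug -> (cell row indices, responses) for the given drugs."""
        df = self.responses.pairs_for_drugs(drug_ids)
        out = {}
        for drug_id, group in df.groupby("drug_id", sort=True):
            rows = np.array([self.cell_index[c] for c in group["cell_id"]])
            out[str(drug_id)] = (rows, group["response"].to_numpy(dtype=float))
        return out


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop when the monitored value fails to improve `patience` times."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0
        self.best_epoch = -1

    def update(self, value: float, epoch: int) -> bool:
        """Record a validation value; return True when training should stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.patience > 0 and self.bad_epochs > self.patience


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _batches(pairs: dict, batch_size: int, rng: np.random.Generator,
             shuffle: bool = True):
    """Batches grouped by drug: (drug_id, cell rows, y)."""
    chunks = []
    for drug_id in sorted(pairs):
        rows, y = pairs[drug_id]
        order = rng.permutation(len(rows)) if shuffle else np.arange(len(rows))
        for start in range(0, len(rows), batch_size):
            sel = order[start:start + batch_size]
            chunks.append((drug_id, rows[sel], y[sel]))
    if shuffle:
        chunks = [chunks[i] for i in rng.permutation(len(chunks))]
    return chunks


def predict_pairs(model, data: TrainingData, drug_ids,
                  return_masks: bool = False):
    """Forward the model over all pairs of the given drugs.

    Returns a DataFrame (drug_id, cell_id, y_true, y_pred) and, optionally,
    a dict drug_id -> (cell_ids, mask matrix).
    """
    model.training = False
    pairs = data.pairs_by_drug(drug_ids)
    rows_out, masks = [], {}
    inv_cell = {i: c for c, i in data.cell_index.items()}
    for drug_id, (rows, y) in pairs.items():
        gt = model.graph_tensors(data.graphs.get(drug_id)) \
            if data.graphs.get(drug_id) is not None else None
        X = data.X_cells[rows]
        yhat, mask = model(gt, data.fingerprints[drug_id], X, return_mask=True)
        for r, yt, yp in zip(rows, y, yhat.data):
            rows_out.append((drug_id, inv_cell[r], yt, yp))
        if return_masks:
            masks[drug_id] = ([inv_cell[r] for r in rows], mask)
    df = pd.DataFrame(rows_out, columns=["drug_id", "cell_id", "y_true", "y_pred"])
    if return_masks:
        return df, masks
    return df


def _val_loss(model, data: TrainingData, drug_ids) -> float:
    df = predict_pairs(model, data, drug_ids)
    return float(np.mean((df["y_true"] - df["y_pred"]) ** 2))


def train_model(model, data: TrainingData, train_drugs, val_drugs,
                epochs: int = 100, patience: int = 5, lr: float = 1e-4,
                batch_size: int = 32, seed: int = 0) -> TrainHistory:
    """Train with Adam on MSE; early-stop on validation MSE.

    Whenever a validation set is given, the best-validation parameter
    state is restored before returning; ``patience=0`` disables the
    stopping rule but keeps best-state selection. Without validation
    drugs the final state is kept.
    """
    if not train_drugs:
        raise ValueError("empty training fold")
    train_pairs = data.pairs_by_drug(train_drugs)
    if not train_pairs:
        raise ValueError("no training pairs for the given drugs")
    rng = np.random.default_rng(seed)
    optimizer = Adam(model.parameters(), lr=lr)
    stopper = EarlyStopper(patience)
    history = TrainHistory()
    graph_cache = {d: (model.graph_tensors(data.graphs[d])
                       if data.graphs.get(d) is not None else None)
                   for d in train_pairs}
    best_state = model.state_dict()
    for epoch in range(epochs):
        model.training = True
        epoch_losses = []
        for drug_id, rows, y in _batches(train_pairs, batch_size, rng):
            X = data.X_cells[rows]
            yhat = model(graph_cache[drug_id], data.fingerprints[drug_id], X)
            diff = yhat - y
            loss = (diff * diff).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_drugs:
            vloss = _val_loss(model, data, val_drugs)
            history.val_loss.append(vloss)
            if vloss < stopper.best:
                best_state = model.state_dict()
            if stopper.update(vloss, epoch):
                logger.info("early stop at epoch %d (best %d)", epoch,
                            stopper.best_epoch)
                break
    if val_drugs:
        model.load_state_dict(best_state)
        history.best_epoch = stopper.best_epoch
    else:
        history.best_epoch = len(history.train_loss) - 1
    return history


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class FoldOutcome:
    fold_id: int
    test_drugs: list[str]
    val_drugs: list[str]
    history: TrainHistory
    predictions: pd.DataFrame
    state: dict


def _model_factory(kind: str, gene_ids, config: ModelConfig, seed: int):
    if kind == "dgdrp":
        return DGDRPModel(gene_ids, config, seed=seed)
    if kind == "all_genes":
        return AllGenesBaseline(gene_ids, config, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def cross_validate(data: TrainingData, folds: FoldAssignment,
                   model_kind: str = "dgdrp",
                   config: ModelConfig | None = None,
                   epochs: int = 100, patience: int = 5, lr: float = 1e-4,
                   batch_size: int = 32, val_fraction: float = 0.1,
                   seed: int = 0) -> tuple[MetricReport, list[FoldOutcome]]:
    """Train one model per fold and evaluate on its blinded test drugs."""
    config = config or ModelConfig()
    outcomes = []
    rng = np.random.default_rng(seed)
    for fold in range(folds.n_folds):
        test_drugs = folds.drugs_in_fold(fold)
        pool = folds.train_drugs(fold)
        n_val = max(1, int(round(val_fraction * len(pool))))
        val_drugs = sorted(list(rng.permutation(pool))[:n_val])
        train_drugs = sorted(set(pool) - set(val_drugs))
        audit_blinding(train_drugs + val_drugs, test_drugs)
        model = _model_factory(model_kind, data.gene_ids, config,
                               seed=seed * 1000 + fold)
        history = train_model(model, data, train_drugs, val_drugs,
                              epochs=epochs, patience=patience, lr=lr,
                              batch_size=batch_size, seed=seed * 1000 + fold)
        preds = predict_pairs(model, data, test_drugs)
        outcomes.append(FoldOutcome(fold, test_drugs, val_drugs, history,
                                    preds, model.state_dict()))
    report = summarize_folds(outcomes)
    return report, outcomes


def summarize_folds(outcomes: list[FoldOutcome]) -> MetricReport:
    per_fold = []
    for oc in outcomes:
        y, yhat = oc.predictions["y_true"], oc.predictions["y_pred"]
        per_fold.append({"fold": oc.fold_id, "rmse": rmse(y, yhat),
                         "pcc": pcc(y, yhat), "scc": scc(y, yhat),
                         "n": len(oc.predictions)})
    df = pd.DataFrame(per_fold)
    return MetricReport(
        rmse=float(df["rmse"].mean()), pcc=float(df["pcc"].mean()),
        scc=float(df["scc"].mean()), n=int(df["n"].sum()), per_fold=per_fold,
        sd={m: float(df[m].std(ddof=0)) for m in ("rmse", "pcc", "scc")},
    )


def audit_blinding(train_drugs, test_drugs) -> None:
    overlap = set(train_drugs) & set(test_drugs)
    if overlap:
        raise AssertionError(f"drug leakage between train and test: {sorted(overlap)}")


def run_ablations(data_by_variant: dict[str, TrainingData],
                  folds: FoldAssignment, **kwargs) -> pd.DataFrame:
    """Run the structural ablations and emit a comparison table."""
    rows = []
    for variant, data in data_by_variant.items():
        report, _ = cross_validate(data, folds, model_kind="dgdrp", **kwargs)
        rows.append({"variant": variant, "rmse": report.rmse,
                     "pcc": report.pcc, "scc": report.scc})
    return pd.DataFrame(rows)
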