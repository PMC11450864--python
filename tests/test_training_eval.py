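"""Folds, metrics, early stopping and the training loop."""

import numpy as np
import pytest
from scipy import stats

from dgdrp.dgdrp_model import DGDRPModel, ModelConfig
from dgdrp.training_eval import (EarlyStopper, TrainingData, audit_blinding,
                                 cross_validate, drug_split_folds, pcc,
                                 predict_pairs, rmse, scc, summarize_folds,
                                 train_model)

SMALL_CFG = ModelConfig(embed_dim=16, k_select=20, gene_id_dim=4,
                        gene_hidden=16, cell_hidden=(64,), drug_hidden=(32,),
                        predictor_hidden=(32, 16))


@pytest.fixture(scope="module")
def small_data(small_bundle):
    b = small_bundle
    return TrainingData.from_inputs(b.expression, b.catalog, b.responses,
                                    b.ppi, b.pathways,
                                    propagation_min_score=600)


class TestFolds:
    def test_even_partition(self, small_bundle):
        folds = drug_split_folds(small_bundle.responses, n_folds=3, seed=0)
        sizes = [len(folds.drugs_in_fold(f)) for f in range(3)]
        assert sorted(sizes) == [2, 2, 2]

    def test_no_drug_in_both_train_and_test(self, small_bundle):
        for seed in range(20):
            n_folds = 2 + seed % 3
            folds = drug_split_folds(small_bundle.responses, n_folds=n_folds,
                                     seed=seed)
            for f in range(n_folds):
                audit_blinding(folds.train_drugs(f), folds.drugs_in_fold(f))
                assert set(folds.train_drugs(f)) | set(folds.drugs_in_fold(f)) \
                    == set(small_bundle.responses.drug_ids)

    def test_same_seed_same_assignment(self, small_bundle):
        a = drug_split_folds(small_bundle.responses, n_folds=3, seed=5)
        b = drug_split_folds(small_bundle.responses, n_folds=3, seed=5)
        assert a.fold_of == b.fold_of

    def test_too_few_drugs_is_an_error(self, small_bundle):
        with pytest.raises(ValueError, match="folds"):
            drug_split_folds(small_bundle.responses, n_folds=10, seed=0)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0
        assert pcc(y, y) == pytest.approx(1.0)
        assert scc(y, y) == pytest.approx(1.0)

    def test_monotone_transform_preserves_spearman_only(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = y ** 3
        assert scc(y, yhat) == pytest.approx(1.0)
        assert pcc(y, yhat) < 1.0

    def test_hand_computed_reversal(self):
        y, yhat = [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]
        assert pcc(y, yhat) == pytest.approx(-1.0)
        assert rmse(y, yhat) == pytest.approx(np.sqrt(8 / 3))

    def test_matches_reference_implementations(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n) + 0.3 * y
            if rng.random() < 0.3:  # exercise tied ranks
                yhat = np.round(yhat, 1)
            assert abs(pcc(y, yhat) - stats.pearsonr(y, yhat)[0]) < 1e-12
            assert abs(scc(y, yhat) - stats.spearmanr(y, yhat)[0]) < 1e-12
            ref_rmse = np.sqrt(np.mean((y - yhat) ** 2))
            assert abs(rmse(y, yhat) - ref_rmse) < 1e-12

    def test_zero_variance_is_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert np.isnan(pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestEarlyStopper:
    def test_strictly_worsening_curve_stops_after_patience_plus_one(self):
        stopper = EarlyStopper(patience=5)
        values = [1.0] + [1.0 + 0.1 * i for i in range(1, 10)]
        stops = [stopper.update(v, i) for i, v in enumerate(values)]
        # 6 evaluations past the best before stopping
        assert stops.index(True) == 6

    def test_improvement_resets_counter(self):
        stopper = EarlyStopper(patience=2)
        seq = [1.0, 1.1, 0.9, 1.0, 1.05, 1.06]
        stops = [stopper.update(v, i) for i, v in enumerate(seq)]
        assert stops == [False, False, False, False, False, True]
        assert stopper.best_epoch == 2


class TestTraining:
    def test_overfit_smoke_loss_drops_below_ten_percent(self, small_data):
        """Learnability: 20 pairs, 500 steps at lr 1e-4 -> loss under 10%."""
        drugs = sorted(small_data.graphs)[:1]  # one drug x 20 cells
        model = DGDRPModel(small_data.gene_ids, SMALL_CFG, seed=0)
        history = train_model(model, small_data, drugs, val_drugs=[],
                              epochs=500, patience=0, lr=1e-4, batch_size=20,
                              seed=0)  # full batch -> 500 steps
        assert history.train_loss[-1] < 0.1 * history.train_loss[0]

    def test_same_seed_reproduces_loss_curve(self, small_data):
        drugs = sorted(small_data.graphs)
        runs = []
        for _ in range(2):
            model = DGDRPModel(small_data.gene_ids, SMALL_CFG, seed=1)
            h = train_model(model, small_data, drugs[:3], [drugs[3]],
                            epochs=3, patience=5, batch_size=8, seed=1)
            runs.append(h.train_loss)
        assert np.allclose(runs[0], runs[1])

    def test_empty_training_fold_is_an_error(self, small_data):
        model = DGDRPModel(small_data.gene_ids, SMALL_CFG, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_model(model, small_data, [], [], epochs=1)

    def test_cross_validate_reports_blinded_folds(self, small_bundle,
                                                  small_data):
        folds = drug_split_folds(small_bundle.responses, n_folds=3, seed=0)
        report, outcomes = cross_validate(small_data, folds,
                                          model_kind="all_genes",
                                          config=SMALL_CFG, epochs=2,
                                          batch_size=10, seed=0)
        assert len(report.per_fold) == 3
        assert report.n == len(small_bundle.responses)
        covered = sorted(d for oc in outcomes for d in oc.test_drugs)
        assert covered == small_bundle.responses.drug_ids
        for oc in outcomes:
            assert not set(oc.test_drugs) & set(oc.predictions["drug_id"]) - \
                set(oc.test_drugs)

    def test_reevaluation_of_fixed_model_is_deterministic(self, small_data):
        model = DGDRPModel(small_data.gene_ids, SMALL_CFG, seed=2)
        drugs = sorted(small_data.graphs)[:2]
        df1 = predict_pairs(model, small_data, drugs)
        df2 = predict_pairs(model, small_data, drugs)
        assert np.array_equal(df1["y_pred"].to_numpy(),
                              df2["y_pred"].to_numpy())

    def test_per_fold_pair_counts_sum(self, small_data, small_bundle):
        folds = drug_split_folds(small_bundle.responses, n_folds=2, seed=1)
        report, outcomes = cross_validate(small_data, folds,
                                          model_kind="all_genes",
                                          config=SMALL_CFG, epochs=1,
                                          batch_size=10, seed=0)
        assert sum(f["n"] for f in report.per_fold) == report.n
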