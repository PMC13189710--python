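"""Scenario splits, training loop mechanics, evaluation metrics."""

import numpy as np
import pytest
from scipy import stats

from synerank.core_data import group_into_lists
from synerank.encoders import ModelConfig
from synerank.experiments import (
    TrainingConfig,
    evaluate,
    evaluate_predictions,
    held_out_lists,
    make_split,
    train,
)
from synerank.synthetic_data import GeneratorConfig, generate_dataset


def _pair_set(dataset, idx):
    return {
        dataset.measurements[i].pair_key()
        for i in idx
        if dataset.measurements[i].drug2_id is not None
    }


def assert_split_contracts(dataset, scenario, n_folds=5, seed=0):
    n = len(dataset.measurements)
    mono = {i for i, m in enumerate(dataset.measurements) if m.drug2_id is None}
    all_tests = []
    for fold in range(n_folds):
        sp = make_split(dataset, scenario, fold, n_folds, seed)
        train_set, test_set = set(sp.train_idx), set(sp.test_idx)
        assert not train_set & test_set
        if scenario in ("S2", "S3"):
            assert not _pair_set(dataset, sp.train_idx) & _pair_set(dataset, sp.test_idx)
            assert not test_set & mono  # monotherapy is never tested
        if scenario == "S3":
            assert not train_set & mono
        else:
            assert train_set | test_set == set(range(n))
        all_tests.append(test_set)
    covered = set().union(*all_tests)
    assert sum(len(t) for t in all_tests) == len(covered)  # disjoint folds
    if scenario == "S1":
        assert covered == set(range(n))
    else:
        assert covered == set(range(n)) - mono


@pytest.mark.parametrize("scenario", ["S1", "S2", "S3"])
def test_split_contracts_on_generated_screens(scenario):
    for seed in range(5):
        cfg = GeneratorConfig(
            n_drugs=5, n_cells=2, n_pairs=6, n_genes=20,
            dose_grid=(1e-7, 1e-6), noise_sd=1.0, seed=seed,
        )
        dataset, _ = generate_dataset(cfg)
        assert_split_contracts(dataset, scenario, seed=seed)


def test_s1_every_matrix_contributes_to_both_sides(tiny_dataset):
    sp = make_split(tiny_dataset, "S1", 0, n_folds=2, seed=0)
    for rl in group_into_lists(tiny_dataset.measurements):
        assert set(rl.indices) & set(sp.train_idx)
        assert set(rl.indices) & set(sp.test_idx)


def test_split_deterministic_given_seed(tiny_dataset):
    a = make_split(tiny_dataset, "S2", 1, seed=42)
    b = make_split(tiny_dataset, "S2", 1, seed=42)
    np.testing.assert_array_equal(a.train_idx, b.train_idx)
    np.testing.assert_array_equal(a.test_idx, b.test_idx)


def test_unknown_scenario_and_fold_rejected(tiny_dataset):
    with pytest.raises(ValueError, match="scenario"):
        make_split(tiny_dataset, "S9", 0)
    with pytest.raises(ValueError, match="fold"):
        make_split(tiny_dataset, "S1", 7, n_folds=5)


# -- training ----------------------------------------------------------------


@pytest.fixture(scope="module")
def smoke_setup():
    cfg = GeneratorConfig(
        n_drugs=5, n_cells=2, n_pairs=5, n_genes=40,
        dose_grid=(1e-7, 1e-6), noise_sd=0.5, seed=1,
    )
    dataset, _ = generate_dataset(cfg)
    split = make_split(dataset, "S1", 0, seed=0)
    mc = ModelConfig.desk(n_genes=30, max_smiles_length=40, seed=0)
    return dataset, split, mc


def test_training_reduces_loss_and_records_history(smoke_setup):
    dataset, split, mc = smoke_setup
    tc = TrainingConfig.desk(epochs=50, seed=0)
    model, history = train(dataset, split, mc, tc)
    assert len(history) == 50
    assert history[-1].total < history[0].total
    assert all(h.total == pytest.approx(h.mse + h.lambda_rank * h.urank) for h in history)


def test_same_seed_training_is_reproducible(smoke_setup):
    dataset, split, mc = smoke_setup
    tc = TrainingConfig.desk(epochs=12, seed=3)
    _, h1 = train(dataset, split, mc, tc)
    _, h2 = train(dataset, split, mc, tc)
    assert h1[-1].total == h2[-1].total


def test_lambda_zero_equals_mse_only_variant(smoke_setup):
    dataset, split, mc = smoke_setup
    h_zero = train(dataset, split, mc, TrainingConfig.desk(epochs=8, lambda_rank=0.0, seed=5))[1]
    h_mse = train(
        dataset, split, mc, TrainingConfig.desk(epochs=8, loss_variant="mse_only", seed=5)
    )[1]
    assert h_zero[-1].total == h_mse[-1].total


def test_empty_training_set_rejected(smoke_setup):
    dataset, split, mc = smoke_setup
    from synerank.experiments import ScenarioSplit

    empty = ScenarioSplit("S1", 0, 5, np.array([], dtype=int), np.asarray(split.test_idx), 0)
    with pytest.raises(ValueError, match="empty"):
        train(dataset, empty, mc, TrainingConfig.desk(epochs=1))


def test_patience_stops_early(smoke_setup):
    dataset, split, mc = smoke_setup
    tc = TrainingConfig.desk(epochs=500, patience=3, seed=0)
    _, history = train(dataset, split, mc, tc)
    assert len(history) < 500


# -- evaluation --------------------------------------------------------------


def test_perfect_predictor_scores_unity(tiny_dataset):
    split = make_split(tiny_dataset, "S1", 0, n_folds=2, seed=0)
    y = np.array([tiny_dataset.measurements[i].response for i in split.test_idx])
    rep = evaluate_predictions(y, y, held_out_lists(tiny_dataset, split))
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.within_list_spearman == pytest.approx(1.0)
    assert rep.ndcg_at_k == pytest.approx(1.0)


def test_constant_predictor_reports_degenerate_zero(tiny_dataset):
    split = make_split(tiny_dataset, "S1", 0, n_folds=2, seed=0)
    y = np.array([tiny_dataset.measurements[i].response for i in split.test_idx])
    rep = evaluate_predictions(y, np.full_like(y, 3.0), held_out_lists(tiny_dataset, split))
    assert rep.pearson_r == 0.0 and rep.degenerate_pearson
    assert rep.within_list_spearman == 0.0


def test_metrics_match_reference_library_on_random_vectors(rng):
    y = rng.normal(size=40)
    p = y + rng.normal(size=40) * 0.5
    lists = [np.arange(0, 20), np.arange(20, 40)]
    rep = evaluate_predictions(y, p, lists, ndcg_k=5)
    assert rep.pearson_r == pytest.approx(stats.pearsonr(y, p).statistic)
    expected_sp = np.mean(
        [stats.spearmanr(y[q], p[q]).statistic for q in lists]
    )
    assert rep.within_list_spearman == pytest.approx(expected_sp)
    assert rep.n_test == 40 and rep.n_test_lists == 2


def test_evaluate_requires_nonempty_test(tiny_dataset):
    from synerank.experiments import ScenarioSplit
    from synerank.encoders import SynergyModel

    model = SynergyModel(ModelConfig.desk(n_genes=30, seed=0))
    empty = ScenarioSplit(
        "S1", 0, 5, np.arange(len(tiny_dataset.measurements)), np.array([], dtype=int), 0
    )
    with pytest.raises(ValueError, match="empty"):
        evaluate(model, tiny_dataset, empty)
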