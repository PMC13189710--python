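"""Leakage-controlled splits, the training loop, and ranking-aware metrics.

Three evaluation scenarios of increasing difficulty:

* S1 — random held-out entries *within* each dose-response matrix: every
  matrix contributes entries to both train and test, so the model
  interpolates inside combinations it has seen.
* S2 — held-out unordered drug pairs: all matrices of a held-out pair,
  across every cell line, go to test. The model must generalise to novel
  combinations. Monotherapy rows stay in training and are never tested.
* S3 — as S2, but monotherapy responses are additionally removed from
  training, the hardest regime.

Cross-validation uses a fixed number of folds (default five); the fold
assignment is a pure function of the seed, so the per-fold test sets
partition the eligible records.

Training is list-aware: batches are assembled from whole response lists so
the listwise term of the hybrid objective is always computed over complete
lists. Targets are standardised to zero mean / unit variance on the
training set (the statistics ride along in the checkpoint and predictions
are mapped back), which keeps the regression and ranking terms on
comparable scales regardless of the raw response units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._nn import Tensor
from .core_data import Dataset, group_into_lists, select_variable_genes
from .encoders import ModelConfig, SynergyModel, dose_position
from .ranking_losses import (
    LossBreakdown,
    mse_loss_t,
    pairwise_ranking_loss_t,
    urank_loss_t,
)

__all__ = [
    "ScenarioSplit",
    "TrainingConfig",
    "EvalReport",
    "make_split",
    "train",
    "evaluate",
    "evaluate_predictions",
    "predict_dataset",
    "held_out_lists",
    "cross_validate",
]

SCENARIOS = ("S1", "S2", "S3")


@dataclass(frozen=True)
class ScenarioSplit:
    scenario: str
    fold: int
    n_folds: int
    train_idx: np.ndarray  # indices into dataset.measurements
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError("train and test sets overlap")


@dataclass
class TrainingConfig:
    """Optimisation settings; defaults are the full-scale configuration."""

    epochs: int = 10_000
    batch_size: int = 256
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    lambda_rank: float = 1.0
    loss_variant: str = "hybrid"  # hybrid | mse_only | pairwise
    gain_mode: str = "exp"
    standardize_targets: bool = True
    swap_augment: bool = False  # random (d1,r1)<->(d2,r2) swaps per epoch
    max_grad_norm: float | None = 25.0  # global-norm clip; catches blow-ups only
    patience: int | None = None  # early stop on train loss; None = fixed epochs
    seed: int = 0

    def __post_init__(self):
        if self.loss_variant not in ("hybrid", "mse_only", "pairwise"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")
        if self.lambda_rank < 0:
            raise ValueError("lambda_rank must be non-negative")

    @classmethod
    def desk(cls, **overrides) -> "TrainingConfig":
        """Small-budget preset for CPU-scale experiments."""
        base = dict(epochs=200, batch_size=256, learning_rate=5e-3, weight_decay=1e-5)
        base.update(overrides)
        return cls(**base)


@dataclass
class EvalReport:
    """Test-set metrics; correlations are on the raw response scale."""

    pearson_r: float
    within_list_spearman: float
    ndcg_at_k: float
    ndcg_k: int
    n_test: int
    n_test_lists: int
    degenerate_pearson: bool = False

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "within_list_spearman": self.within_list_spearman,
            f"ndcg_at_{self.ndcg_k}": self.ndcg_at_k,
            "n_test": self.n_test,
            "n_test_lists": self.n_test_lists,
            "degenerate_pearson": self.degenerate_pearson,
        }


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def make_split(
    dataset: Dataset,
    scenario: str,
    fold: int,
    n_folds: int = 5,
    seed: int = 0,
) -> ScenarioSplit:
    """Deterministic scenario split; same seed => folds partition the data.

    S1 assigns each response list's entries round-robin to folds after a
    seeded within-list shuffle (stratified per matrix). S2 partitions the
    unordered combination pairs into fold groups; every record of a
    held-out pair, in every cell line, is test. S3 reuses S2's partition
    and drops all monotherapy records from training.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold {fold} out of range [0, {n_folds})")
    rng = np.random.default_rng(seed)
    lists = group_into_lists(dataset.measurements)
    lists = sorted(lists, key=lambda rl: (rl.drug1_id, rl.drug2_id or "", rl.cell_id))
    n = len(dataset.measurements)

    if scenario == "S1":
        fold_of = np.empty(n, dtype=int)
        for rl in lists:
            perm = rng.permutation(rl.n)
            labels = np.arange(rl.n) % n_folds
            for pos, lab in zip(perm, labels):
                fold_of[rl.indices[pos]] = lab
        test = np.flatnonzero(fold_of == fold)
        train = np.flatnonzero(fold_of != fold)
        return ScenarioSplit(scenario, fold, n_folds, train, test, seed)

    # S2 / S3: partition unordered combination pairs
    pair_keys = sorted({(rl.drug1_id, rl.drug2_id) for rl in lists if not rl.is_monotherapy})
    perm = rng.permutation(len(pair_keys))
    group_of = {pair_keys[p]: g % n_folds for g, p in enumerate(perm)}
    test_mask = np.zeros(n, dtype=bool)
    mono_mask = np.zeros(n, dtype=bool)
    for rl in lists:
        if rl.is_monotherapy:
            mono_mask[rl.indices] = True
        elif group_of[(rl.drug1_id, rl.drug2_id)] == fold:
            test_mask[rl.indices] = True
    train_mask = ~test_mask
    if scenario == "S3":
        train_mask &= ~mono_mask
    return ScenarioSplit(
        scenario, fold, n_folds, np.flatnonzero(train_mask), np.flatnonzero(test_mask), seed
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class _Indexed:
    """Measurement table resolved to integer indices for fast batching."""

    d1: np.ndarray
    d2: np.ndarray
    cell: np.ndarray
    dose1: np.ndarray
    dose2: np.ndarray
    response: np.ndarray
    unique_smiles: list[str | None]
    expr_cols: np.ndarray  # (n_cells, n_genes)


def _index_dataset(dataset: Dataset, model_config: ModelConfig) -> _Indexed:
    expr = dataset.expression
    if len(expr.gene_ids) != model_config.n_genes:
        expr = select_variable_genes(expr, model_config.n_genes)
    expr_values = expr.values
    if model_config.standardize_expression:
        mu = expr_values.mean(axis=1, keepdims=True)
        sd = expr_values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        expr_values = (expr_values - mu) / sd
    drug_ids = [d.drug_id for d in dataset.drugs]
    drug_pos = {did: i for i, did in enumerate(drug_ids)}
    null_pos = len(drug_ids)
    cell_pos = {cid: i for i, cid in enumerate(expr.cell_ids)}
    ms = dataset.measurements
    return _Indexed(
        d1=np.array([drug_pos[m.drug1_id] for m in ms], dtype=np.intp),
        d2=np.array(
            [null_pos if m.drug2_id is None else drug_pos[m.drug2_id] for m in ms],
            dtype=np.intp,
        ),
        cell=np.array([cell_pos[m.cell_id] for m in ms], dtype=np.intp),
        dose1=np.array([m.dose1 for m in ms]),
        dose2=np.array([m.dose2 for m in ms]),
        response=np.array([m.response for m in ms]),
        unique_smiles=[dataset.smiles_by_id[d] for d in drug_ids] + [None],
        expr_cols=expr_values.T.copy(),
    )


def _rank_term(variant: str, s: np.ndarray, o: Tensor, gain_mode: str) -> Tensor:
    if variant == "pairwise":
        return pairwise_ranking_loss_t(s, o)
    return urank_loss_t(s, o, gain_mode)


def train(
    dataset: Dataset,
    split: ScenarioSplit,
    model_config: ModelConfig,
    training_config: TrainingConfig,
    callback: Callable[[int, LossBreakdown], None] | None = None,
) -> tuple[SynergyModel, list[LossBreakdown]]:
    """Train a model on the split's training records.

    Returns the model and one averaged :class:`LossBreakdown` per epoch.
    Raises on an empty training set and on non-finite losses (with the
    offending epoch in the message). Fixed seeds give bit-identical runs
    on CPU.
    """
    if len(split.train_idx) == 0:
        raise ValueError("training set is empty")
    tc = training_config
    model = SynergyModel(model_config)
    idx = _index_dataset(dataset, model_config)

    train_records = [dataset.measurements[i] for i in split.train_idx]
    train_lists = group_into_lists(train_records)
    # positions of each list's entries inside split.train_idx
    list_slices = [np.asarray(rl.indices, dtype=np.intp) for rl in train_lists]

    y = idx.response[split.train_idx]
    if tc.standardize_targets:
        model.target_mean = float(y.mean())
        model.target_sd = float(y.std()) or 1.0
    y_std = (y - model.target_mean) / model.target_sd

    t_d1 = idx.d1[split.train_idx]
    t_d2 = idx.d2[split.train_idx]
    t_cell = idx.cell[split.train_idx]
    t_pos1 = dose_position(idx.dose1[split.train_idx], model_config.dose_scale_mode)
    t_pos2 = dose_position(idx.dose2[split.train_idx], model_config.dose_scale_mode)
    # the sinusoidal dose encoding has no parameters: encode each record once
    if model_config.dose_encoding == "sin":
        sin1 = model.encode_doses(t_pos1).data
        sin2 = model.encode_doses(t_pos2).data
    else:
        sin1 = sin2 = None

    drug_rows = model.drug_input_rows(idx.unique_smiles)
    lambda_rank = 0.0 if tc.loss_variant == "mse_only" else tc.lambda_rank

    opt = model.make_optimizer(tc.learning_rate, tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    history: list[LossBreakdown] = []
    best = math.inf
    stale = 0

    null_pos = len(dataset.drugs)
    combo_mask = t_d2 != null_pos

    order = np.arange(len(train_lists))
    for epoch in range(tc.epochs):
        rng.shuffle(order)
        if tc.swap_augment:
            swap = combo_mask & (rng.random(t_d1.size) < 0.5)
            e_d1 = np.where(swap, t_d2, t_d1)
            e_d2 = np.where(swap, t_d1, t_d2)
            e_pos1 = np.where(swap, t_pos2, t_pos1)
            e_pos2 = np.where(swap, t_pos1, t_pos2)
            if sin1 is not None:
                e_sin1 = np.where(swap[:, None], sin2, sin1)
                e_sin2 = np.where(swap[:, None], sin1, sin2)
            else:
                e_sin1 = e_sin2 = None
        else:
            e_d1, e_d2, e_pos1, e_pos2 = t_d1, t_d2, t_pos1, t_pos2
            e_sin1, e_sin2 = sin1, sin2
        batches: list[list[int]] = [[]]
        count = 0
        for li in order:
            if count >= tc.batch_size and batches[-1]:
                batches.append([])
                count = 0
            batches[-1].append(li)
            count += list_slices[li].size
        ep_mse = ep_rank = ep_total = 0.0
        n_batch_records = 0
        for batch_lists in batches:
            sel = np.concatenate([list_slices[li] for li in batch_lists])
            drug_e = model.encode_drug_inputs(drug_rows)
            cell_e = model.encode_cells(idx.expr_cols)
            if model_config.center_embeddings:
                # centre on the real-drug library mean (null row excluded from
                # the mean but shifted by it, like every other row)
                d_mean = drug_e.slice_rows(0, null_pos).mean(axis=0)
                drug_e = drug_e + (-d_mean)
                cell_e = cell_e + (-cell_e.mean(axis=0))
            dose_e = (Tensor(e_sin1[sel]), Tensor(e_sin2[sel])) if e_sin1 is not None else None
            o = model.forward_indexed(
                drug_e, e_d1[sel], e_d2[sel], cell_e, t_cell[sel],
                e_pos1[sel], e_pos2[sel], dose_embeds=dose_e,
            )
            s_batch = y_std[sel]
            mse = mse_loss_t(s_batch, o)
            if lambda_rank > 0:
                offset = 0
                rank_sum: Tensor | None = None
                for li in batch_lists:
                    m = list_slices[li].size
                    o_l = o.slice_rows(offset, offset + m)
                    term = _rank_term(tc.loss_variant, s_batch[offset : offset + m], o_l, tc.gain_mode)
                    rank_sum = term if rank_sum is None else rank_sum + term
                    offset += m
                rank = rank_sum / float(len(batch_lists))
            else:
                rank = Tensor(0.0)
            total = mse + Tensor(lambda_rank) * rank
            if not np.isfinite(total.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            if tc.max_grad_norm is not None:
                gsq = sum(
                    float(np.sum(p.grad * p.grad)) for p in opt.params if p.grad is not None
                )
                gnorm = math.sqrt(gsq)
                if gnorm > tc.max_grad_norm:
                    scale = tc.max_grad_norm / gnorm
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            w = sel.size
            ep_mse += mse.item() * w
            ep_rank += rank.item() * w
            ep_total += total.item() * w
            n_batch_records += w
        bd = LossBreakdown(
            mse=ep_mse / n_batch_records,
            urank=ep_rank / n_batch_records,
            total=ep_total / n_batch_records,
            lambda_rank=lambda_rank,
        )
        history.append(bd)
        if callback is not None:
            callback(epoch, bd)
        if tc.patience is not None:
            if bd.total < best - 1e-6:
                best, stale = bd.total, 0
            else:
                stale += 1
                if stale >= tc.patience:
                    break
    if model_config.center_embeddings:
        model.drug_embed_center = (
            model.encode_drug_inputs(drug_rows).data[:null_pos].mean(axis=0)
        )
        model.cell_embed_center = model.encode_cells(idx.expr_cols).data.mean(axis=0)
    return model, history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def predict_dataset(
    model: SynergyModel, dataset: Dataset, indices: Sequence[int] | None = None
) -> np.ndarray:
    """Predictions (raw response scale) for the given measurement indices."""
    idx = _index_dataset(dataset, model.config)
    sel = np.arange(len(dataset.measurements)) if indices is None else np.asarray(indices)
    return model.predict_batch(
        idx.unique_smiles,
        idx.d1[sel],
        idx.d2[sel],
        idx.expr_cols,
        idx.cell[sel],
        idx.dose1[sel],
        idx.dose2[sel],
    )


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    lists: Sequence[Sequence[int]],
    ndcg_k: int = 5,
) -> EvalReport:
    """Metrics from raw prediction vectors.

    ``lists`` holds, for each test response list, the positions of its
    entries within y_true/y_pred. Pearson r is computed over all entries;
    a constant vector makes it undefined and is reported as 0 with the
    degenerate flag set. Within-list Spearman and NDCG average over lists
    with at least two entries (constant within-list predictions score 0).
    """
    from sklearn.metrics import ndcg_score

    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty test set")

    degenerate = np.ptp(y_pred) == 0 or np.ptp(y_true) == 0
    if degenerate:
        pearson = 0.0
    else:
        pearson = float(stats.pearsonr(y_true, y_pred).statistic)

    spearmans: list[float] = []
    ndcgs: list[float] = []
    n_lists = 0
    for pos in lists:
        pos = np.asarray(pos, dtype=np.intp)
        if pos.size < 2:
            continue
        n_lists += 1
        st, sp = y_true[pos], y_pred[pos]
        if np.ptp(st) == 0 or np.ptp(sp) == 0:  # constant list: rank undefined
            rho = 0.0
        else:
            rho = stats.spearmanr(st, sp).statistic
        spearmans.append(0.0 if not np.isfinite(rho) else float(rho))
        rel = st - st.min()
        rel = rel / rel.max() if rel.max() > 0 else rel
        k = min(ndcg_k, pos.size)
        ndcgs.append(float(ndcg_score(rel[None, :], sp[None, :], k=k)))
    return EvalReport(
        pearson_r=pearson,
        within_list_spearman=float(np.mean(spearmans)) if spearmans else math.nan,
        ndcg_at_k=float(np.mean(ndcgs)) if ndcgs else math.nan,
        ndcg_k=ndcg_k,
        n_test=int(y_true.size),
        n_test_lists=n_lists,
        degenerate_pearson=bool(degenerate),
    )


def held_out_lists(dataset: Dataset, split: ScenarioSplit) -> list[np.ndarray]:
    """Positions (within split.test_idx) of each test response list's entries."""
    records = [dataset.measurements[i] for i in split.test_idx]
    return [np.asarray(rl.indices, dtype=np.intp) for rl in group_into_lists(records)]


def evaluate(
    model: SynergyModel, dataset: Dataset, split: ScenarioSplit, ndcg_k: int = 5
) -> EvalReport:
    if len(split.test_idx) == 0:
        raise ValueError("test set is empty")
    y_true = np.array([dataset.measurements[i].response for i in split.test_idx])
    y_pred = predict_dataset(model, dataset, split.test_idx)
    return evaluate_predictions(y_true, y_pred, held_out_lists(dataset, split), ndcg_k)


def cross_validate(
    dataset: Dataset,
    scenario: str,
    model_config: ModelConfig,
    training_config: TrainingConfig,
    n_folds: int = 5,
    seed: int = 0,
    ndcg_k: int = 5,
) -> tuple[list[EvalReport], dict[str, tuple[float, float]]]:
    """Train/evaluate each fold; returns per-fold reports and mean +- sd."""
    reports = []
    for fold in range(n_folds):
        split = make_split(dataset, scenario, fold, n_folds, seed)
        tc = replace(training_config, seed=training_config.seed + fold)
        model, _ = train(dataset, split, model_config, tc)
        reports.append(evaluate(model, dataset, split, ndcg_k))
    summary = {}
    for key in ("pearson_r", "within_list_spearman", "ndcg_at_k"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        summary[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return reports, summary
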