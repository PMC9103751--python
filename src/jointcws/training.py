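"""Training loops for the joint model and the two-stage baseline.

Protocol: Adam (lr 0.001), up to 50 epochs, mini-batches of 32, gradient
clipping at global norm 5, and best-on-validation-loss checkpointing —
the weights restored at the end are those of the epoch with the minimum
validation objective.  The joint mode backpropagates the weighted sum of
both task losses through the shared trunk in a single pass per batch;
weighting-strategy updates run per step (gradnorm, uncertainty) or per
epoch (dwa).

The non-joint baseline trains in two stages with no shared gradient:
stage 1 fits the Bi-LSTM tagger alone; stage 2 fits the TextCNN
classifier on sentences re-represented with stage-1 *predicted* boundary
tags (an 8-dim learned tag embedding concatenated to the character
embedding) on train, validation and test alike.  Keeping the classifier
architecture otherwise identical isolates the effect of joint learning.
Because stage 2 re-embeds every sentence after stage 1 has already
processed it, the baseline performs two feature-extraction passes per
sentence against the joint model's one; the counter is surfaced in the
run result.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, no_grad
from .corpus import (
    AnnotatedRecord,
    Batch,
    Vocabulary,
    build_vocabulary,
    make_batches,
    split_dataset,
)
from .evaluation import EvalReport, classification_metrics, roc_auc, segmentation_metrics
from .losses import (
    WeightState,
    class_loss,
    joint_loss,
    masked_tag_loss,
    update_weights_dwa,
    update_weights_gradnorm,
    update_weights_uncertainty,
)
from .model import JointModel, JointModelConfig, save_checkpoint

__all__ = [
    "TrainConfig",
    "RunResult",
    "Adam",
    "train_joint",
    "train_two_stage",
    "train",
    "run_cross_validation",
    "grid_search_weights",
]

logger = logging.getLogger(__name__)

PAD_TAG_INDEX = 3  # boundary-feature row for padded positions


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 0.001
    batch_size: int = 32
    strategy: str = "gradnorm"
    fixed_weights: tuple[float, float] | None = None  # fixed strategy only
    folds: int = 7
    seed: int = 0
    mode: str = "joint"  # joint | two_stage | classification_only
    grad_clip: float = 5.0
    checkpoint_path: str | None = None
    log_path: str | None = None
    # optional early stop once validation accuracies clear these thresholds
    stop_at_val_accuracy: tuple[float | None, float | None] | None = None

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in ("joint", "two_stage", "classification_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RunResult:
    mode: str
    best_epoch: int
    best_val_loss: float
    per_epoch_log: list[dict]
    test_segmentation: EvalReport | None
    test_classification: EvalReport | None
    model: JointModel
    vocabulary: Vocabulary
    best_checkpoint_path: str | None = None
    feature_extraction_passes_per_sentence: int = 1
    # per-item test-set outcomes, for the statistical comparison machinery
    test_labels: np.ndarray | None = None
    test_predictions: np.ndarray | None = None
    test_scores: np.ndarray | None = None
    stage1: "RunResult | None" = None

    @property
    def test_correct(self) -> np.ndarray:
        return self.test_predictions == self.test_labels


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _apply_grad_masks(params: Sequence[Tensor]) -> None:
    for p in params:
        if p.grad is not None and p.grad_mask is not None:
            p.grad *= p.grad_mask


def _clip_gradients(params: Sequence[Tensor], max_norm: float) -> bool:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
        return True
    return False


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"training diverged: {what} is {value} at epoch {epoch}; "
            "lower the learning rate or inspect the corpus"
        )


def _stage1_tags(model: JointModel, batch: Batch) -> np.ndarray:
    """Predicted tag indices with the padding row for masked positions."""
    tags = model.predict_tags(batch)
    return np.where(batch.mask, tags, PAD_TAG_INDEX)


def _evaluate(
    model: JointModel,
    records: Sequence[AnnotatedRecord],
    vocabulary: Vocabulary,
    batch_size: int,
    state: WeightState | None = None,
    tagger_model: JointModel | None = None,
):
    """Losses, metrics and per-item classification outcomes on a split."""
    batches = make_batches(records, vocabulary, batch_size)
    tag_gold, tag_pred, tag_masks = [], [], []
    labels, preds, scores = [], [], []
    loss0_sum = loss0_n = 0.0
    loss1_sum = loss1_n = 0.0
    for batch in batches:
        boundary = None
        if model.config.use_boundary_features:
            boundary = _stage1_tags(tagger_model, batch)
        with no_grad():
            out = model.forward(batch, boundary_tags=boundary)
        if out.tag_scores is not None:
            L0 = masked_tag_loss(out.tag_scores, batch.tag_targets, batch.mask)
            n0 = int(batch.mask.sum())
            loss0_sum += L0.item() * n0
            loss0_n += n0
            tag_gold.append(batch.tag_targets)
            tag_pred.append(out.tag_scores.data.argmax(axis=2))
            tag_masks.append(batch.mask)
        if out.class_scores is not None:
            L1 = class_loss(out.class_scores, batch.labels)
            loss1_sum += L1.item() * batch.size
            loss1_n += batch.size
            labels.append(batch.labels)
            preds.append(out.class_scores.data.argmax(axis=1))
            sc = out.class_scores.data
            shifted = np.exp(sc - sc.max(axis=1, keepdims=True))
            scores.append((shifted / shifted.sum(axis=1, keepdims=True))[:, 1])
    L0 = loss0_sum / loss0_n if loss0_n else None
    L1 = loss1_sum / loss1_n if loss1_n else None
    if state is not None and L0 is not None and L1 is not None:
        objective = joint_loss(L0, L1, state).item()
    else:
        objective = L0 if L1 is None else L1
    seg_report = cls_report = None
    if tag_gold:
        seg_report = segmentation_metrics(
            np.concatenate([g.ravel() for g in tag_gold]),
            np.concatenate([p.ravel() for p in tag_pred]),
            np.concatenate([m.ravel() for m in tag_masks]),
        )
    out_labels = out_preds = out_scores = None
    if labels:
        out_labels = np.concatenate(labels)
        out_preds = np.concatenate(preds)
        out_scores = np.concatenate(scores)
        cls_report = classification_metrics(out_labels, out_preds)
        if len(np.unique(out_labels)) == 2:
            cls_report.roc_points, cls_report.auc = roc_auc(out_labels, out_scores)
    return {
        "L0": L0,
        "L1": L1,
        "objective": objective,
        "segmentation": seg_report,
        "classification": cls_report,
        "labels": out_labels,
        "predictions": out_preds,
        "scores": out_scores,
    }


def _write_log(path: str, rows: list[dict]) -> None:
    if not rows:
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def _fit(
    model: JointModel,
    train_records: Sequence[AnnotatedRecord],
    val_records: Sequence[AnnotatedRecord],
    vocabulary: Vocabulary,
    config: TrainConfig,
    state: WeightState,
    use_tagger: bool,
    use_classifier: bool,
    tagger_model: JointModel | None = None,
) -> tuple[int, float, list[dict]]:
    """Shared epoch loop; returns (best_epoch, best_val_loss, log rows) and
    leaves the best-validation weights loaded in ``model``."""
    params = model.parameters() + state.trainable_parameters()
    optimizer = Adam(params, lr=config.learning_rate)
    best_val = np.inf
    best_epoch = -1
    best_state = [p.data.copy() for p in model.parameters()]
    rows: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        if state.strategy == "dwa":
            update_weights_dwa(state, epoch)
        batches = make_batches(
            train_records, vocabulary, config.batch_size,
            shuffle_seed=config.seed * 100_003 + epoch,
        )
        sum0 = sum1 = 0.0
        n_clipped = 0
        for batch in batches:
            boundary = None
            if model.config.use_boundary_features:
                boundary = _stage1_tags(tagger_model, batch)
            out = model.forward(
                batch,
                training=True,
                run_tagger=use_tagger,
                run_classifier=use_classifier,
                boundary_tags=boundary,
            )
            L0 = L1 = None
            if use_tagger:
                L0 = masked_tag_loss(out.tag_scores, batch.tag_targets, batch.mask)
                sum0 += L0.item()
            if use_classifier:
                L1 = class_loss(out.class_scores, batch.labels)
                sum1 += L1.item()
            if L0 is not None and L1 is not None:
                if state.strategy == "gradnorm":
                    norms = []
                    for task_loss in (L0, L1):
                        optimizer.zero_grad()
                        task_loss.backward()
                        g = model.embedding.grad
                        norms.append(0.0 if g is None else float(np.sqrt((g**2).sum())))
                    update_weights_gradnorm(
                        state, (L0.item(), L1.item()), tuple(norms), step
                    )
                objective = joint_loss(L0, L1, state)
            else:
                objective = L0 if L1 is None else L1
            _check_finite(objective.item(), "training loss", epoch)
            optimizer.zero_grad()
            objective.backward()
            _apply_grad_masks(params)
            if _clip_gradients(params, config.grad_clip):
                n_clipped += 1
            optimizer.step()
            if state.strategy == "uncertainty":
                update_weights_uncertainty(state)
            step += 1
        n_batches = max(len(batches), 1)
        if state.strategy == "dwa":
            state.loss_history.append((sum0 / n_batches, sum1 / n_batches))
        val = _evaluate(
            model, val_records, vocabulary, config.batch_size,
            state if (use_tagger and use_classifier) else None,
            tagger_model=tagger_model,
        )
        val_objective = float(val["objective"])
        _check_finite(val_objective, "validation loss", epoch)
        rows.append(
            {
                "epoch": epoch,
                "train_L0": sum0 / n_batches if use_tagger else "",
                "train_L1": sum1 / n_batches if use_classifier else "",
                "r0": state.r0,
                "r1": state.r1,
                "val_loss": val_objective,
                "val_tag_accuracy": (
                    val["segmentation"].accuracy if val["segmentation"] else ""
                ),
                "val_class_accuracy": (
                    val["classification"].accuracy if val["classification"] else ""
                ),
                "clipped_batches": n_clipped,
            }
        )
        if val_objective < best_val:
            best_val = val_objective
            best_epoch = epoch
            best_state = [p.data.copy() for p in model.parameters()]
        if config.stop_at_val_accuracy is not None:
            tag_goal, cls_goal = config.stop_at_val_accuracy
            tag_ok = (
                tag_goal is None
                or (val["segmentation"] is not None
                    and val["segmentation"].accuracy >= tag_goal)
            )
            cls_ok = (
                cls_goal is None
                or (val["classification"] is not None
                    and val["classification"].accuracy >= cls_goal)
            )
            if tag_ok and cls_ok:
                # keep the stopping epoch's weights even if an earlier epoch
                # had a lower validation loss
                best_val = val_objective
                best_epoch = epoch
                best_state = [p.data.copy() for p in model.parameters()]
                break
    model.load_state_arrays(best_state)
    return best_epoch, best_val, rows


def _prepare(corpus, train_config, splits):
    train_config.validate()
    if splits is None:
        splits = split_dataset(corpus, seed=train_config.seed)
    train_records, val_records, test_records = splits
    vocabulary = build_vocabulary(train_records)
    return train_records, val_records, test_records, vocabulary


def _with_vocab(model_config: JointModelConfig, vocabulary: Vocabulary, **changes):
    if model_config.vocab_size <= 0:
        changes["vocab_size"] = len(vocabulary)
    return replace(model_config, **changes)


def train_joint(
    corpus: Sequence[AnnotatedRecord],
    model_config: JointModelConfig,
    train_config: TrainConfig,
    splits=None,
) -> RunResult:
    """Joint multi-task training: one forward/backward pass per batch."""
    train_records, val_records, test_records, vocabulary = _prepare(
        corpus, train_config, splits
    )
    model = JointModel(_with_vocab(model_config, vocabulary, seed=model_config.seed))
    fixed = train_config.fixed_weights or (None, None)
    state = WeightState.create(train_config.strategy, r0=fixed[0], r1=fixed[1])
    best_epoch, best_val, rows = _fit(
        model, train_records, val_records, vocabulary, train_config, state,
        use_tagger=True, use_classifier=True,
    )
    test = _evaluate(model, test_records, vocabulary, train_config.batch_size, state)
    if train_config.log_path:
        _write_log(train_config.log_path, rows)
    checkpoint = None
    if train_config.checkpoint_path:
        save_checkpoint(train_config.checkpoint_path, model, vocabulary)
        checkpoint = train_config.checkpoint_path
    return RunResult(
        mode="joint",
        best_epoch=best_epoch,
        best_val_loss=best_val,
        per_epoch_log=rows,
        test_segmentation=test["segmentation"],
        test_classification=test["classification"],
        model=model,
        vocabulary=vocabulary,
        best_checkpoint_path=checkpoint,
        feature_extraction_passes_per_sentence=1,
        test_labels=test["labels"],
        test_predictions=test["predictions"],
        test_scores=test["scores"],
    )


def train_two_stage(
    corpus: Sequence[AnnotatedRecord],
    model_config: JointModelConfig,
    train_config: TrainConfig,
    splits=None,
) -> RunResult:
    """Non-joint baseline: tagger first, then a classifier over predicted tags."""
    train_records, val_records, test_records, vocabulary = _prepare(
        corpus, train_config, splits
    )
    # stage 1: segmentation only
    cfg1 = _with_vocab(
        model_config, vocabulary, include_classifier=False, seed=model_config.seed
    )
    tagger = JointModel(cfg1)
    state1 = WeightState.create("fixed", r0=1.0, r1=0.0)
    ep1, val1, rows1 = _fit(
        tagger, train_records, val_records, vocabulary, train_config, state1,
        use_tagger=True, use_classifier=False,
    )
    # stage 2: classification over characters + stage-1 predicted boundary tags
    cfg2 = _with_vocab(
        model_config, vocabulary,
        include_tagger=False, use_boundary_features=True,
        seed=model_config.seed + 1,
    )
    classifier = JointModel(cfg2)
    state2 = WeightState.create("fixed", r0=0.0, r1=1.0)
    ep2, val2, rows2 = _fit(
        classifier, train_records, val_records, vocabulary, train_config, state2,
        use_tagger=False, use_classifier=True, tagger_model=tagger,
    )
    seg_test = _evaluate(tagger, test_records, vocabulary, train_config.batch_size)
    cls_test = _evaluate(
        classifier, test_records, vocabulary, train_config.batch_size,
        tagger_model=tagger,
    )
    rows = [dict(r, stage=1) for r in rows1] + [dict(r, stage=2) for r in rows2]
    if train_config.log_path:
        _write_log(train_config.log_path, rows)
    checkpoint = None
    if train_config.checkpoint_path:
        save_checkpoint(train_config.checkpoint_path, classifier, vocabulary)
        checkpoint = train_config.checkpoint_path
    stage1_result = RunResult(
        mode="two_stage/stage1",
        best_epoch=ep1,
        best_val_loss=val1,
        per_epoch_log=rows1,
        test_segmentation=seg_test["segmentation"],
        test_classification=None,
        model=tagger,
        vocabulary=vocabulary,
    )
    return RunResult(
        mode="two_stage",
        best_epoch=ep2,
        best_val_loss=val2,
        per_epoch_log=rows,
        test_segmentation=seg_test["segmentation"],
        test_classification=cls_test["classification"],
        model=classifier,
        vocabulary=vocabulary,
        best_checkpoint_path=checkpoint,
        feature_extraction_passes_per_sentence=2,
        test_labels=cls_test["labels"],
        test_predictions=cls_test["predictions"],
        test_scores=cls_test["scores"],
        stage1=stage1_result,
    )


def train_classification_only(
    corpus, model_config, train_config, splits=None
) -> RunResult:
    """One-stage ablation: TextCNN over raw characters, no segmentation signal."""
    train_records, val_records, test_records, vocabulary = _prepare(
        corpus, train_config, splits
    )
    cfg = _with_vocab(
        model_config, vocabulary, include_tagger=False, seed=model_config.seed
    )
    model = JointModel(cfg)
    state = WeightState.create("fixed", r0=0.0, r1=1.0)
    best_epoch, best_val, rows = _fit(
        model, train_records, val_records, vocabulary, train_config, state,
        use_tagger=False, use_classifier=True,
    )
    test = _evaluate(model, test_records, vocabulary, train_config.batch_size)
    if train_config.log_path:
        _write_log(train_config.log_path, rows)
    return RunResult(
        mode="classification_only",
        best_epoch=best_epoch,
        best_val_loss=best_val,
        per_epoch_log=rows,
        test_segmentation=None,
        test_classification=test["classification"],
        model=model,
        vocabulary=vocabulary,
        test_labels=test["labels"],
        test_predictions=test["predictions"],
        test_scores=test["scores"],
    )


_MODES = {
    "joint": train_joint,
    "two_stage": train_two_stage,
    "classification_only": train_classification_only,
}


def train(corpus, model_config, train_config, splits=None) -> RunResult:
    """Dispatch on ``train_config.mode``."""
    train_config.validate()
    return _MODES[train_config.mode](corpus, model_config, train_config, splits)


def run_cross_validation(
    corpus: Sequence[AnnotatedRecord],
    model_config: JointModelConfig,
    train_config: TrainConfig,
) -> dict:
    """Repeated reseeded splits (the configured fold count), metric averages.

    A fixed 60/10/30 split is not a standard k-fold partition, so "k-fold"
    is realized as k independent reseeded splits whose metrics are averaged.
    """
    if train_config.folds < 2:
        raise ValueError("folds must be >= 2")
    fold_seeds = [train_config.seed + 1000 * (k + 1) for k in range(train_config.folds)]
    results = []
    for fold, fold_seed in enumerate(fold_seeds):
        cfg = replace(train_config, seed=fold_seed, checkpoint_path=None, log_path=None)
        result = train(corpus, model_config, cfg)
        results.append(result)
        logger.info("fold %d (seed %d) done", fold, fold_seed)
    metrics: dict[str, list[float]] = {}
    for r in results:
        for task, report in (
            ("segmentation", r.test_segmentation),
            ("classification", r.test_classification),
        ):
            if report is None:
                continue
            for name in ("accuracy", "specificity", "sensitivity"):
                metrics.setdefault(f"{task}_{name}", []).append(getattr(report, name))
            if report.auc is not None:
                metrics.setdefault(f"{task}_auc", []).append(report.auc)
    summary = {
        name: {"mean": float(np.mean(v)), "std": float(np.std(v, ddof=1))}
        for name, v in metrics.items()
    }
    return {"fold_seeds": fold_seeds, "results": results, "summary": summary}


def grid_search_weights(
    corpus: Sequence[AnnotatedRecord],
    model_config: JointModelConfig,
    train_config: TrainConfig,
    grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
) -> dict:
    """Exhaustive (r0, r1) grid for the fixed strategy, selected by
    validation classification accuracy."""
    splits = split_dataset(corpus, seed=train_config.seed)
    table = []
    best = None
    for r0 in grid:
        for r1 in grid:
            cfg = replace(
                train_config, strategy="fixed", fixed_weights=(r0, r1),
                checkpoint_path=None, log_path=None,
            )
            result = train_joint(corpus, model_config, cfg, splits=splits)
            val_acc = max(
                (row["val_class_accuracy"] for row in result.per_epoch_log),
                default=0.0,
            )
            entry = {"r0": r0, "r1": r1, "val_class_accuracy": float(val_acc)}
            table.append(entry)
            if best is None or entry["val_class_accuracy"] > best[0]["val_class_accuracy"]:
                best = (entry, result)
    return {"table": table, "best": best[0], "best_result": best[1]}
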