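"""Joint training of the contrastive and classification objectives.

Each training step draws a batch of N source images, augments each twice
into a double-viewed batch, and minimises

    L = L_ce + λ · L_contrastive

where the cross-entropy runs over the class logits of all 2N views and the
contrastive term (self-supervised, SupCon, or angular-margin) runs over the
2N unit-norm projections.  Training is single-stage: both heads learn
together.  At a configurable cadence the alignment and uniformity of the
current batch's projections are logged; at every epoch end the model is
scored on the validation split and the epoch with the highest validation
accuracy (earliest on ties) is retained as the best model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from .autodiff import Tensor, logsumexp_rows
from .data import (
    AugmentationPolicy,
    DoubleViewBatch,
    LabeledImageTable,
    SplitTable,
    load_eval_batch,
    make_double_view_batch,
)
from .metrics import ClassificationReport, alignment, uniformity, classification_report
from .models import Adam, ModelBundle
from .losses import MarginConfig

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "train",
    "evaluate",
    "export_embeddings",
    "batch_alignment_uniformity",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol knobs (reference defaults: 20 epochs, batch 64,
    lr 2e-4, Adam, τ=0.05, m_u=0.2, m_v=0.1, λ=1)."""

    epochs: int = 20
    batch_size: int = 64
    lr: float = 2e-4
    optimizer: str = "adam"
    margin: MarginConfig = field(default_factory=MarginConfig)
    loss: str = "angular_margin"  # self | supcon | angular_margin
    task: str = "multiclass"
    image_size: int = 224
    seed: int = 0
    log_cadence: int = 10
    log_first_steps: int = 1500
    max_steps: int | None = None
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy.default)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")
        if self.loss not in ("self", "supcon", "angular_margin"):
            raise ValueError(f"unknown loss kind {self.loss!r}")


@dataclass
class TrainingHistory:
    """Per-step losses, logged alignment/uniformity, per-epoch validation."""

    steps: list[dict] = field(default_factory=list)
    metrics: list[dict] = field(default_factory=list)
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for kind, records in (("step", self.steps), ("metric", self.metrics),
                                  ("epoch", self.epochs)):
                for rec in records:
                    fh.write(json.dumps({"kind": kind, **rec}) + "\n")
            fh.write(json.dumps({"kind": "best_epoch", "epoch": self.best_epoch}) + "\n")


def _log_softmax(logits: Tensor) -> Tensor:
    n, k = logits.shape
    lse = logsumexp_rows(logits, np.ones((n, k), dtype=bool))
    return logits - lse.reshape(n, 1)


def _nll(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over samples, computed stably from logits."""
    logp = _log_softmax(logits)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * Tensor(onehot)).sum(axis=1).mean()


def _contrastive_terms(z: Tensor, batch: DoubleViewBatch, cfg: TrainConfig) -> Tensor:
    part = L.partition_anchors(batch.pairing, batch.labels)
    if cfg.loss == "self":
        return L.nce_terms_t(z, part.u_mask, part.a_mask, cfg.margin.tau)
    if cfg.loss == "supcon":
        return L.nce_terms_t(z, part.p_mask, part.a_mask, cfg.margin.tau)
    return L.angular_margin_terms_t(z, part, cfg.margin)


def batch_alignment_uniformity(
    z: np.ndarray, pairing: np.ndarray
) -> tuple[float, float]:
    """Alignment over the sibling pairs (one per source) and uniformity over
    all 2N projected views of the batch."""
    pairing = np.asarray(pairing)
    firsts = np.flatnonzero(np.arange(len(pairing)) < pairing)
    return alignment(z[firsts], z[pairing[firsts]]), uniformity(z)


def train(
    model: ModelBundle,
    table: LabeledImageTable,
    split: SplitTable,
    cfg: TrainConfig,
) -> tuple[ModelBundle, TrainingHistory]:
    """Optimise the combined objective; return the best-epoch model.

    Batches are drawn without replacement within an epoch (seeded shuffle);
    a trailing partial batch is skipped if smaller than 2 sources.
    """
    train_rows = split.subset(table, "train")
    val_rows = split.subset(table, "val")
    if len(train_rows) == 0 or len(val_rows) == 0:
        raise ValueError("empty train or validation partition")
    n_batch = min(cfg.batch_size, len(train_rows))
    opt = Adam(model.trainable(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    best_acc, best_state = -1.0, None
    step = 0
    done = False
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_rows))
        for start in range(0, len(order) - 1, n_batch):
            chunk = order[start : start + n_batch]
            if len(chunk) < 2:
                continue
            batch = make_double_view_batch(
                train_rows.subset(chunk), cfg.policy,
                seed=int(rng.integers(2**31)), size=cfg.image_size,
            )
            _, z, logits = model.forward(batch.views)
            ce = _nll(logits, batch.labels)
            contrast = _contrastive_terms(z, batch, cfg).mean()
            total = ce + cfg.margin.lam * contrast
            opt.zero_grad()
            total.backward()
            opt.step()
            history.steps.append(
                {"step": step, "epoch": epoch, "total": total.item(),
                 "ce": ce.item(), "contrastive": contrast.item()}
            )
            if step % cfg.log_cadence == 0 and step < cfg.log_first_steps:
                a, u = batch_alignment_uniformity(z.data, batch.pairing)
                history.metrics.append(
                    {"step": step, "alignment": a, "uniformity": u}
                )
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        report = evaluate(model, val_rows, cfg.task, cfg.image_size)
        history.epochs.append({"epoch": epoch, "val": json.loads(report.to_json())})
        if report.accuracy > best_acc:
            best_acc = report.accuracy
            best_state = model.copy()
            history.best_epoch = epoch
        if done:
            break
    return best_state if best_state is not None else model, history


def evaluate(
    model: ModelBundle,
    rows: LabeledImageTable,
    task: str = "multiclass",
    image_size: int | None = None,
    batch: int = 64,
) -> ClassificationReport:
    """Deterministic inference (resize only) and the five-metric report."""
    if len(rows) == 0:
        raise ValueError("no rows to evaluate")
    size = image_size or model.spec.image_size
    rasters = load_eval_batch(rows, size=size)
    probs = []
    for start in range(0, len(rasters), batch):
        _, _, logits = model.forward(rasters[start : start + batch])
        e = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
        probs.append(e / e.sum(axis=1, keepdims=True))
    probs = np.vstack(probs)
    pred = probs.argmax(axis=1)
    truth = rows.grades
    if task == "binary":
        return classification_report(probs[:, 1], pred, truth, task="binary")
    return classification_report(probs, pred, truth, task="multiclass")


def export_embeddings(
    model: ModelBundle,
    rows: LabeledImageTable,
    path: str | Path,
    image_size: int | None = None,
) -> Path:
    """Write (id, label, r_1..r_D) encoder representations as TSV.

    The projection head is dropped: these are the representations a
    downstream 2-D projector (e.g. UMAP) consumes.
    """
    path = Path(path)
    size = image_size or model.spec.image_size
    rasters = load_eval_batch(rows, size=size)
    reps = []
    for start in range(0, len(rasters), 64):
        r, _, _ = model.forward(rasters[start : start + 64])
        reps.append(r.data)
    reps = np.vstack(reps)
    try:
        with open(path, "w") as fh:
            header = ["id", "label"] + [f"v{k + 1}" for k in range(reps.shape[1])]
            fh.write("\t".join(header) + "\n")
            for rid, label, vec in zip(rows.ids, rows.grades, reps):
                fh.write(
                    "\t".join([str(rid), str(int(label))] + [f"{v:.8g}" for v in vec])
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing embeddings to {path}: {exc}") from exc
    return path
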