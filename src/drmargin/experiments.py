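"""Run orchestration and the two ablation harnesses.

A *run* is described by a flat YAML config (paths + training protocol); the
harnesses wrap it:

* **margin ablation** — a grid over ``m_v`` values and ``m_u`` multipliers
  (``m_u = multiplier × m_v``); the 1.0 column is the SupCon-like
  degenerate case where both margins coincide.  One short training run per
  cell, shared seed; the cell value is test-set AUC in percent.
* **augmentation-pair ablation** — a symmetric grid over six augmentation
  operators; diagonal cells train with a single operator, off-diagonal
  cells with the pair.  Only the 21 unique cells are trained; the matrix is
  mirrored.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    AugmentationPolicy,
    LabeledImageTable,
    SplitSpec,
    map_binary,
    read_label_csv,
    stratified_split,
)
from .losses import MarginConfig
from .models import ModelSpec, build_model
from .pipeline import TrainConfig, evaluate, train
from .synth import SyntheticImageConfig, generate_dataset

__all__ = [
    "RunConfig",
    "MarginGridSpec",
    "AugPairGridSpec",
    "load_run_config",
    "run_train",
    "margin_ablation",
    "aug_ablation",
    "AUGMENTATION_OPERATORS",
]

AUGMENTATION_OPERATORS = (
    "random_resized_crop",
    "horizontal_flip",
    "grayscale",
    "vertical_flip",
    "color_jitter",
    "rotation",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one training run needs: paths + protocol."""

    data_dir: str = "."
    label_csv: str = "labels.csv"
    output_dir: str = "runs/out"
    dataset_tag: str = "dataset"
    task: str = "multiclass"
    loss: str = "angular_margin"
    epochs: int = 20
    batch_size: int = 64
    lr: float = 2e-4
    tau: float = 0.05
    m_u: float = 0.2
    m_v: float = 0.1
    lam: float = 1.0
    image_size: int = 224
    d_e: int = 64
    proj_hidden: int = 128
    d_p: int = 128
    encoder: str = "small_cnn"
    seed: int = 0
    log_cadence: int = 10
    max_steps: int | None = None

    def train_config(self, policy: AugmentationPolicy | None = None) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            margin=MarginConfig(self.m_u, self.m_v, self.tau, self.lam),
            loss=self.loss,
            task=self.task,
            image_size=self.image_size,
            seed=self.seed,
            log_cadence=self.log_cadence,
            max_steps=self.max_steps,
            policy=policy if policy is not None else AugmentationPolicy.default(),
        )

    def model_spec(self, n_classes: int) -> ModelSpec:
        return ModelSpec(
            encoder=self.encoder,
            d_e=self.d_e,
            proj_hidden=self.proj_hidden,
            d_p=self.d_p,
            n_classes=n_classes,
            image_size=self.image_size,
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Read a flat YAML config; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**doc)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _load_table(cfg: RunConfig) -> LabeledImageTable:
    table = read_label_csv(
        Path(cfg.data_dir) / cfg.label_csv, cfg.data_dir, tag=cfg.dataset_tag
    )
    if cfg.task == "binary":
        table = map_binary(table)
    return table


def run_train(cfg: RunConfig, policy: AugmentationPolicy | None = None) -> dict:
    """One full training run: checkpoint, history, manifest, test report."""
    table = _load_table(cfg)  # validate inputs before touching the output dir
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_run_config(cfg, out / "effective_config.yaml")
    split = stratified_split(table, SplitSpec(seed=cfg.seed, task=cfg.task))
    split.to_manifest(out / "split_manifest.csv")
    n_classes = 2 if cfg.task == "binary" else 5
    model = build_model(cfg.model_spec(n_classes), seed=cfg.seed)
    _log(f"training {cfg.loss} on {len(table)} rows ({cfg.task})")
    model, history = train(model, table, split, cfg.train_config(policy))
    model.save(out / "checkpoint.npz")
    history.to_jsonl(out / "history.jsonl")
    report = evaluate(model, split.subset(table, "test"), cfg.task, cfg.image_size)
    report.to_json(out / "test_report.json")
    _log(f"test accuracy {report.accuracy:.2f}  AUC {report.auc:.2f}")
    return {"report": report, "history": history, "model": model, "split": split}


def alignment_comparison(
    work_dir: str | Path,
    base_seed: int = 1,
    n_seeds: int = 3,
    steps: int = 300,
    n_per_grade: int = 40,
    image_size: int = 64,
    batch_size: int = 16,
    last_k: int = 50,
) -> dict:
    """SupCon vs angular-margin alignment on the synthetic 5-class set.

    Mirrors the alignment-trace comparison of the two objectives: one
    synthetic dataset (``n_per_grade`` images per grade), then for each of
    ``n_seeds`` seeds two identically-seeded training runs — SupCon
    (no margins) and angular margin (m_u=0.2, m_v=0.1) — for ``steps``
    optimisation steps, logging batch alignment every 10 steps.  The
    summary statistic per run is the mean alignment over the last
    ``last_k`` logged points (or all of them, if fewer were produced).
    """
    work_dir = Path(work_dir)
    table = generate_dataset(
        SyntheticImageConfig(size=image_size, seed=base_seed),
        (n_per_grade,) * 5,
        work_dir / "data",
    )
    split = stratified_split(table, SplitSpec(seed=base_seed))
    n_train = len(split.subset(table, "train"))
    steps_per_epoch = max(1, len(range(0, n_train - 1, batch_size)))
    epochs = -(-steps // steps_per_epoch)
    per_seed = []
    for k in range(n_seeds):
        seed = (base_seed + k) % 2**31
        means = {}
        for loss_kind, margin in (
            ("supcon", MarginConfig(0.0, 0.0, 0.05, 1.0)),
            ("angular_margin", MarginConfig(0.2, 0.1, 0.05, 1.0)),
        ):
            model = build_model(
                ModelSpec(image_size=image_size, n_classes=5), seed=seed
            )
            cfg = TrainConfig(
                epochs=epochs, batch_size=batch_size, margin=margin,
                loss=loss_kind, image_size=image_size, seed=seed,
                max_steps=steps,
            )
            _log(f"alignment run seed={seed} loss={loss_kind}")
            trained, history = train(model, table, split, cfg)
            trace = [m["alignment"] for m in history.metrics]
            means[loss_kind] = float(np.mean(trace[-last_k:]))
            if loss_kind == "angular_margin":
                report = evaluate(
                    trained, split.subset(table, "train"), "multiclass", image_size
                )
                means["am_train_accuracy"] = report.accuracy
        per_seed.append({"seed": seed, **means})
    wins = sum(s["angular_margin"] <= s["supcon"] for s in per_seed)
    return {"per_seed": per_seed, "wins": wins, "n_seeds": n_seeds}


@dataclass(frozen=True)
class MarginGridSpec:
    """m_v values × m_u multipliers grid; cell metric is test AUC."""

    m_v_values: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.4)
    multipliers: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)

    def __post_init__(self) -> None:
        if min(self.multipliers) < 1.0 or max(self.multipliers) > 3.0:
            raise ValueError("m_u multipliers must lie in [1.0, 3.0]")


def margin_ablation(
    cfg: RunConfig, grid: MarginGridSpec = MarginGridSpec()
) -> pd.DataFrame:
    """Train one short run per (m_v, multiplier) cell; shared seed.

    Returns a DataFrame indexed by m_v with one column per multiplier.  The
    multiplier-1.0 column has m_u = m_v: the SupCon-like degenerate case.
    """
    rows = {}
    for m_v in grid.m_v_values:
        row = {}
        for mult in grid.multipliers:
            cell = replace(
                cfg, m_u=round(mult * m_v, 10), m_v=m_v, loss="angular_margin",
                output_dir=str(Path(cfg.output_dir) / f"mv{m_v}_x{mult}"),
            )
            _log(f"margin cell m_v={m_v} m_u={cell.m_u}")
            row[mult] = run_train(cell)["report"].auc
        rows[m_v] = row
    table = pd.DataFrame(rows).T
    table.index.name = "m_v"
    table.columns.name = "m_u_multiplier"
    return table


@dataclass(frozen=True)
class AugPairGridSpec:
    """Symmetric operator-pair grid; diagonal = single operator."""

    operators: tuple[str, ...] = AUGMENTATION_OPERATORS


def aug_ablation(cfg: RunConfig, grid: AugPairGridSpec = AugPairGridSpec()) -> pd.DataFrame:
    """Train the 21 unique operator pairs and mirror into a 6×6 AUC table."""
    ops = grid.operators
    k = len(ops)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            policy = (
                AugmentationPolicy.single(ops[i])
                if i == j
                else AugmentationPolicy.pair(ops[i], ops[j])
            )
            cell = replace(
                cfg, output_dir=str(Path(cfg.output_dir) / f"aug_{ops[i]}__{ops[j]}")
            )
            _log(f"augmentation cell ({ops[i]}, {ops[j]})")
            auc_val = run_train(cell, policy=policy)["report"].auc
            mat[i, j] = mat[j, i] = auc_val
    return pd.DataFrame(mat, index=ops, columns=ops)
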