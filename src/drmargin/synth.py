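"""Synthetic fundus-like imagery and sphere-clustered embedding fixtures.

Real fundus photographs show a roughly circular retinal disc whose lesion
load (bright exudates, dark hemorrhages) grows with disease severity.  The
generator reproduces exactly that class-conditional structure — a disc on a
dark background with a grade-dependent number of lesion marks — and nothing
else: no vessel trees, no optic-disc anatomy, no camera vignetting.  It
exists so the full pipeline (file I/O, splitting, augmentation, training,
evaluation) runs end-to-end without downloading clinical datasets.

The cluster generator produces unit-norm embeddings around K class
centroids with a controllable angular spread, giving the loss layer a
fixture whose geometry is known in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LabeledImageTable, read_label_csv, write_label_csv
from .losses import make_pairing, normalize_rows

__all__ = [
    "SyntheticImageConfig",
    "SyntheticClusterConfig",
    "generate_fundus_like",
    "generate_dataset",
    "generate_sphere_clusters",
]


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Knobs of the fundus-like image generator.

    ``lesion_ranges[g]`` is the inclusive (low, high) lesion-count range for
    grade ``g``; the ranges are non-decreasing in grade and grade 0 draws
    zero lesions, mirroring the severity scale.
    """

    size: int = 64
    lesion_ranges: tuple[tuple[int, int], ...] = (
        (0, 0), (1, 3), (4, 7), (8, 11), (12, 16),
    )
    disc_radius_frac: float = 0.45
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise level must be nonnegative")
        los = [r[0] for r in self.lesion_ranges]
        his = [r[1] for r in self.lesion_ranges]
        if any(l > h for l, h in zip(los, his)):
            raise ValueError("each lesion range needs low <= high")
        if any(b < a for a, b in zip(los, los[1:])) or any(
            b < a for a, b in zip(his, his[1:])
        ):
            raise ValueError("lesion count ranges must be non-decreasing in grade")


@dataclass(frozen=True)
class SyntheticClusterConfig:
    """K classes of unit-norm embeddings with a given angular spread (radians)."""

    n_classes: int = 5
    per_class: int = 4
    dim: int = 16
    spread: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.spread <= 0:
            raise ValueError("angular spread must be positive")


def generate_fundus_like(grade: int, cfg: SyntheticImageConfig, seed: int) -> np.ndarray:
    """One synthetic fundus-like raster for a severity grade.

    A reddish circular disc on a dark background; ``n`` lesion marks with
    ``n`` drawn uniformly from the grade's range — bright yellowish spots
    (exudate-like) and dark blobs (hemorrhage-like) in equal proportion.
    Returns (size, size, 3) uint8; identical seed ⇒ identical raster.
    """
    if not 0 <= grade < len(cfg.lesion_ranges):
        raise ValueError(f"grade {grade} out of range 0-{len(cfg.lesion_ranges) - 1}")
    rng = np.random.default_rng(seed)
    s = cfg.size
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    r_disc = cfg.disc_radius_frac * s
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= r_disc**2
    img = np.zeros((s, s, 3), dtype=np.float64)
    base = np.array([0.62, 0.28, 0.12]) * rng.uniform(0.9, 1.1)  # retina tint
    img[disc] = base
    lo, hi = cfg.lesion_ranges[grade]
    n_lesions = int(rng.integers(lo, hi + 1))
    for k in range(n_lesions):
        # rejection-free placement: sample uniformly inside the disc
        rho = r_disc * 0.85 * np.sqrt(rng.random())
        phi = rng.uniform(0, 2 * np.pi)
        ly, lx = c + rho * np.sin(phi), c + rho * np.cos(phi)
        rad = rng.uniform(0.02, 0.05) * s
        mask = (yy - ly) ** 2 + (xx - lx) ** 2 <= rad**2
        if k % 2 == 0:  # bright exudate-like spot
            img[mask & disc] = np.array([0.95, 0.85, 0.35])
        else:  # dark hemorrhage-like blob
            img[mask & disc] = np.array([0.25, 0.05, 0.04])
    img += rng.normal(0.0, cfg.noise, img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def generate_dataset(
    cfg: SyntheticImageConfig,
    counts: dict[int, int] | tuple[int, ...],
    out_dir: str | Path,
    tag: str = "synthetic",
) -> LabeledImageTable:
    """Write a synthetic labelled dataset: PNGs + label CSV + config JSON.

    ``counts`` gives how many images to draw per grade.  The label CSV uses
    the ``id_code``/``diagnosis`` dialect so it round-trips through
    :func:`drmargin.data.read_label_csv`.
    """
    if not isinstance(counts, dict):
        counts = {g: int(c) for g, c in enumerate(counts)}
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be nonnegative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(cfg.seed)
    ids, grades = [], []
    for grade in sorted(counts):
        for k in range(counts[grade]):
            img_seed = int(root.integers(2**31))
            rid = f"syn_g{grade}_{k:04d}"
            Image.fromarray(generate_fundus_like(grade, cfg, img_seed)).save(
                out_dir / f"{rid}.png"
            )
            ids.append(rid)
            grades.append(grade)
    import pandas as pd

    table = LabeledImageTable(
        pd.DataFrame(
            {"id": ids, "path": [str(out_dir / f"{i}.png") for i in ids], "grade": grades}
        ),
        tag=tag,
    )
    write_label_csv(table, out_dir / "labels.csv")
    with open(out_dir / "generator_config.json", "w") as fh:
        json.dump(asdict(cfg) | {"counts": {str(g): c for g, c in counts.items()}}, fh, indent=2)
    return read_label_csv(out_dir / "labels.csv", out_dir, tag=tag)


def generate_sphere_clusters(
    cfg: SyntheticClusterConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Double-viewed unit-norm embeddings clustered by class.

    K random unit centroids; every *source* contributes two views obtained
    by perturbing its centroid with Gaussian noise of magnitude
    ``tan(spread)`` in the tangent space and re-normalising, so the angular
    deviation from the centroid is on the order of ``spread``.  Returns
    (matrix 2N×D, labels 2N, pairing) in the [firsts; seconds] layout.
    """
    rng = np.random.default_rng(cfg.seed)
    centroids = normalize_rows(rng.normal(size=(cfg.n_classes, cfg.dim)))
    n = cfg.n_classes * cfg.per_class
    sigma = np.tan(cfg.spread)
    if not np.isfinite(sigma) or sigma > 1e6:
        raise ValueError("angular spread too large; perturbed rows would degenerate")

    def views() -> np.ndarray:
        out = np.empty((n, cfg.dim))
        for k in range(n):
            mu = centroids[k // cfg.per_class]
            noise = rng.normal(size=cfg.dim) * sigma / np.sqrt(cfg.dim)
            noise -= (noise @ mu) * mu  # tangent-space perturbation
            out[k] = mu + noise
        return normalize_rows(out)

    firsts, seconds = views(), views()
    labels = np.repeat(np.arange(cfg.n_classes), cfg.per_class)
    return (
        np.vstack([firsts, seconds]),
        np.concatenate([labels, labels]),
        make_pairing(n),
    )
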