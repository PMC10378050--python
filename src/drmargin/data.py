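"""Dataset I/O, label mapping, stratified splitting and view augmentation.

The on-disk dataset convention is a directory of PNG/JPEG fundus images plus
a CSV label table (``id_code``/``diagnosis`` columns by default) with integer
severity grades 0–4: No DR, Mild, Moderate, Severe, Proliferative (PDR).
Detection collapses the scale to No-DR (0) vs DR (1–4); grading keeps all
five classes.

Splitting is stratified 70/15/15 per class with a deterministic rounding
rule (see :func:`split_counts`), and batches are *double-viewed*: each source
image contributes two independently augmented views, stacked as
``[first views; second views]`` so view ``i`` is paired with ``(i+N) mod 2N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance

from .losses import make_pairing

__all__ = [
    "LabeledImageTable",
    "SplitSpec",
    "SplitTable",
    "AugmentationPolicy",
    "DoubleViewBatch",
    "read_label_csv",
    "write_label_csv",
    "map_binary",
    "split_counts",
    "stratified_split",
    "apply_augmentation",
    "make_double_view_batch",
    "GRADE_NAMES",
]

GRADE_NAMES = ("No DR", "Mild", "Moderate", "Severe", "PDR")


@dataclass(frozen=True)
class LabeledImageTable:
    """Rows of (id, image path, grade) plus a dataset tag."""

    frame: pd.DataFrame  # columns: id, path, grade
    tag: str = "dataset"

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def grades(self) -> np.ndarray:
        return self.frame["grade"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    def class_sizes(self) -> dict[int, int]:
        return self.frame["grade"].value_counts().sort_index().to_dict()

    def subset(self, mask_or_index) -> "LabeledImageTable":
        return replace(self, frame=self.frame.loc[mask_or_index].reset_index(drop=True))


def read_label_csv(
    path: str | Path,
    image_dir: str | Path | None = None,
    id_column: str = "id_code",
    grade_column: str = "diagnosis",
    image_suffix: str = ".png",
    tag: str = "dataset",
    check_paths: bool = True,
) -> LabeledImageTable:
    """Read an APTOS-dialect label CSV into a validated table.

    Grades must be integers in 0–4 and identifiers unique; violations are
    reported with the offending (1-based, header-exclusive) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    for col in (id_column, grade_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    grades = pd.to_numeric(df[grade_column], errors="coerce")
    bad = grades.isna() | (grades != grades.round()) | (grades < 0) | (grades > 4)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path} row {row + 1}: invalid grade {df[grade_column].iloc[row]!r} "
            "(expected an integer 0-4)"
        )
    dup = df[id_column].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(f"{path} row {row + 1}: duplicate id {df[id_column].iloc[row]!r}")
    image_dir = Path(image_dir) if image_dir is not None else path.parent
    frame = pd.DataFrame(
        {
            "id": df[id_column].astype(str),
            "path": [str(image_dir / f"{i}{image_suffix}") for i in df[id_column]],
            "grade": grades.astype(int),
        }
    )
    if check_paths:
        missing = [p for p in frame["path"] if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"{len(missing)} image file(s) missing, e.g. {missing[0]}")
    return LabeledImageTable(frame, tag=tag)


def write_label_csv(
    table: LabeledImageTable,
    path: str | Path,
    id_column: str = "id_code",
    grade_column: str = "diagnosis",
) -> None:
    pd.DataFrame({id_column: table.ids, grade_column: table.grades}).to_csv(
        path, index=False
    )


def map_binary(table: LabeledImageTable) -> LabeledImageTable:
    """Collapse severity grades to detection labels: 0 → No DR, 1–4 → DR."""
    frame = table.frame.copy()
    frame["grade"] = (frame["grade"] > 0).astype(int)
    return replace(table, frame=frame)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split fractions plus the seed controlling membership."""

    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    seed: int = 0
    task: str = "multiclass"

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class SplitTable:
    """Per-class counts and the membership of every row."""

    counts: pd.DataFrame  # index: class; columns: train/val/test
    assignment: pd.Series  # id -> "train" | "val" | "test"

    def ids(self, part: str) -> np.ndarray:
        return self.assignment.index[self.assignment == part].to_numpy()

    def subset(self, table: LabeledImageTable, part: str) -> LabeledImageTable:
        mask = table.frame["id"].map(self.assignment).eq(part)
        return table.subset(mask.to_numpy())

    def to_manifest(self, path: str | Path) -> None:
        self.assignment.rename("split").rename_axis("id").to_csv(path)


def split_counts(n: int) -> tuple[int, int, int]:
    """Deterministic 70/15/15 class allocation.

    holdout = round-half-even(3n/10); val = round-half-even(holdout/2);
    test = holdout − val; train = n − holdout.  Computed in exact rational
    arithmetic so float representation of 0.3 cannot flip a boundary case.
    """
    holdout = round(Fraction(3 * n, 10))
    val = round(Fraction(holdout, 2))
    return n - holdout, val, holdout - val


def stratified_split(table: LabeledImageTable, spec: SplitSpec) -> SplitTable:
    """Split each class 70/15/15 with seeded within-class shuffling.

    Counts depend only on the class size; membership depends on the seed.
    Classes with fewer than 2 rows go entirely to the training set with a
    warning (a holdout of size 0 or an unsplittable singleton).
    """
    if spec.train != 0.70 or spec.val != 0.15:
        raise ValueError("only the 70/15/15 protocol is supported")
    rng = np.random.default_rng(spec.seed)
    rows: dict[str, str] = {}
    records = []
    for cls, group in table.frame.groupby("grade"):
        n = len(group)
        if n < 2:
            warnings.warn(f"class {cls} has {n} row(s); assigning all to train")
            tr, va, te = n, 0, 0
        else:
            tr, va, te = split_counts(n)
        order = group["id"].to_numpy()[rng.permutation(n)]
        for i, rid in enumerate(order):
            rows[rid] = "train" if i < tr else ("val" if i < tr + va else "test")
        records.append({"class": cls, "train": tr, "val": va, "test": te})
    counts = pd.DataFrame(records).set_index("class")
    assignment = pd.Series({rid: rows[rid] for rid in table.ids}, name="split")
    return SplitTable(counts, assignment)


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class AugmentationPolicy:
    """Ordered list of stochastic image operators with parameters.

    Supported operators: ``random_resized_crop`` (``scale`` range),
    ``horizontal_flip`` / ``vertical_flip`` / ``grayscale`` (``p``),
    ``color_jitter`` (``strength``), ``rotation`` (``degrees``).
    """

    ops: tuple[tuple[str, dict], ...] = ()

    def __post_init__(self) -> None:
        for name, params in self.ops:
            if name not in _OPERATORS:
                raise ValueError(f"unknown augmentation operator {name!r}")
            p = params.get("p")
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability {p} outside [0, 1]")
            scale = params.get("scale")
            if scale is not None and not (0.0 < scale[0] <= scale[1] <= 1.0):
                raise ValueError(f"{name}: crop scale range {scale} outside (0, 1]")

    @staticmethod
    def default() -> "AugmentationPolicy":
        """Crop + two flips — the reference training recipe."""
        return AugmentationPolicy(
            (
                ("random_resized_crop", {"scale": (0.8, 1.0)}),
                ("horizontal_flip", {"p": 0.5}),
                ("vertical_flip", {"p": 0.5}),
            )
        )

    @staticmethod
    def single(name: str) -> "AugmentationPolicy":
        return AugmentationPolicy(((name, dict(DEFAULT_PARAMS[name])),))

    @staticmethod
    def pair(a: str, b: str) -> "AugmentationPolicy":
        ops = [(a, dict(DEFAULT_PARAMS[a]))]
        if b != a:
            ops.append((b, dict(DEFAULT_PARAMS[b])))
        return AugmentationPolicy(tuple(ops))


#: crop scale and flip probabilities follow the reference protocol; the
#: jitter strength, rotation range and grayscale probability are this
#: package's own defaults for the ablation harness.
DEFAULT_PARAMS = {
    "random_resized_crop": {"scale": (0.8, 1.0)},
    "horizontal_flip": {"p": 0.5},
    "vertical_flip": {"p": 0.5},
    "grayscale": {"p": 0.2},
    "color_jitter": {"strength": 0.4},
    "rotation": {"degrees": 30.0},
}


def _op_crop(img: Image.Image, rng: np.random.Generator, params: dict) -> Image.Image:
    lo, hi = params.get("scale", (0.8, 1.0))
    w, h = img.size
    area = w * h * rng.uniform(lo, hi)
    aspect = np.exp(rng.uniform(np.log(3 / 4), np.log(4 / 3)))
    cw = min(w, int(round(np.sqrt(area * aspect))))
    ch = min(h, int(round(np.sqrt(area / aspect))))
    x0 = int(rng.integers(0, w - cw + 1))
    y0 = int(rng.integers(0, h - ch + 1))
    return img.crop((x0, y0, x0 + cw, y0 + ch))


def _op_hflip(img, rng, params):
    return img.transpose(Image.FLIP_LEFT_RIGHT) if rng.random() < params.get("p", 0.5) else img


def _op_vflip(img, rng, params):
    return img.transpose(Image.FLIP_TOP_BOTTOM) if rng.random() < params.get("p", 0.5) else img


def _op_gray(img, rng, params):
    return img.convert("L").convert("RGB") if rng.random() < params.get("p", 0.2) else img


def _op_jitter(img, rng, params):
    s = params.get("strength", 0.4)
    for enhancer in (ImageEnhance.Brightness, ImageEnhance.Contrast, ImageEnhance.Color):
        img = enhancer(img).enhance(rng.uniform(max(0.0, 1 - s), 1 + s))
    return img


def _op_rotate(img, rng, params):
    deg = params.get("degrees", 30.0)
    return img.rotate(rng.uniform(-deg, deg), resample=Image.BILINEAR)


_OPERATORS = {
    "random_resized_crop": _op_crop,
    "horizontal_flip": _op_hflip,
    "vertical_flip": _op_vflip,
    "grayscale": _op_gray,
    "color_jitter": _op_jitter,
    "rotation": _op_rotate,
}


def apply_augmentation(
    image: Image.Image | np.ndarray,
    policy: AugmentationPolicy,
    seed: int | np.random.Generator,
    size: int = 224,
) -> np.ndarray:
    """Run the policy's operators in order and resize to ``size``×``size``.

    Returns an (H, W, 3) uint8 raster.  The same seed yields a bit-identical
    output (all randomness flows through one ``numpy`` generator).
    """
    if isinstance(image, np.ndarray):
        image = Image.fromarray(image)
    image = image.convert("RGB")
    if image.size[0] == 0 or image.size[1] == 0:
        raise ValueError("empty image raster")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for name, params in policy.ops:
        image = _OPERATORS[name](image, rng, params)
    image = image.resize((size, size), Image.BILINEAR)
    return np.asarray(image, dtype=np.uint8)


@dataclass(frozen=True)
class DoubleViewBatch:
    """2N augmented views with sibling pairing and per-view labels."""

    views: np.ndarray  # (2N, 3, S, S) float64 in [0, 1]
    pairing: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...] = field(default=())

    @property
    def n_sources(self) -> int:
        return len(self.pairing) // 2


def _load_raster(path: str) -> Image.Image:
    with Image.open(path) as img:
        return img.convert("RGB")


def make_double_view_batch(
    table: LabeledImageTable,
    policy: AugmentationPolicy,
    seed: int,
    size: int = 224,
) -> DoubleViewBatch:
    """Two stochastic views per source image, stacked [firsts; seconds].

    Sibling views use distinct sub-seeds drawn from one seeded generator, so
    the two views of a source differ while the whole batch is reproducible.
    """
    n = len(table)
    if n < 2:
        raise ValueError("a contrastive batch needs at least 2 source images")
    root = np.random.default_rng(seed)
    firsts, seconds = [], []
    for _, row in table.frame.iterrows():
        img = _load_raster(row["path"])
        firsts.append(apply_augmentation(img, policy, np.random.default_rng(root.integers(2**31)), size))
        seconds.append(apply_augmentation(img, policy, np.random.default_rng(root.integers(2**31)), size))
    views = np.stack(firsts + seconds).astype(np.float64) / 255.0
    views = views.transpose(0, 3, 1, 2)  # NHWC -> NCHW
    labels = np.concatenate([table.grades, table.grades])
    return DoubleViewBatch(views, make_pairing(n), labels, tuple(table.ids) * 2)


def load_eval_batch(table: LabeledImageTable, size: int = 224) -> np.ndarray:
    """Deterministic inference rasters: resize only, no augmentation."""
    if len(table) == 0:
        raise ValueError("no rows to evaluate")
    rasters = [
        np.asarray(_load_raster(p).resize((size, size), Image.BILINEAR), dtype=np.float64) / 255.0
        for p in table.frame["path"]
    ]
    return np.stack(rasters).transpose(0, 3, 1, 2)
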