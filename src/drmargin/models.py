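"""Encoder, projection head, classifier head and the Adam optimizer.

The architecture follows the contrastive-classification framework: an
encoder maps a raster to a representation ``r`` normalised onto the unit
hypersphere; a 2-layer perceptron projection head maps ``r`` to the
contrastive space ``z`` (also unit-norm); a linear classifier maps ``r`` to
class logits.  The projection head exists only for the contrastive loss and
plays no part in inference.

The built-in encoder is a 4-block convolutional network (conv3×3 → ReLU →
2×2 average pool, channel widths 8/16/32/64) sized for desk-scale runs;
deeper backbones (ResNet-class, representation width 2048) satisfy the same
contract and can be registered externally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .autodiff import Tensor, avg_pool2, conv2d
from .losses import normalize_rows_t

__all__ = ["ModelSpec", "ModelBundle", "Adam", "build_model", "load_model"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description.

    ``d_e`` is the representation width (64 for the small CNN; 2048 for a
    ResNet-class backbone), ``proj_hidden``/``d_p`` the projection head
    sizes (reference values 2048/128; desk-scale runs shrink the hidden
    layer), ``n_classes`` the classifier output width.
    """

    encoder: str = "small_cnn"
    d_e: int = 64
    proj_hidden: int = 128
    d_p: int = 128
    n_classes: int = 5
    image_size: int = 64
    channels: tuple[int, int, int, int] = (8, 16, 32, 64)

    def __post_init__(self) -> None:
        if self.image_size % 16:
            raise ValueError("image size must be divisible by 16 (four 2x2 pools)")
        if min(self.d_e, self.proj_hidden, self.d_p, self.n_classes) < 1:
            raise ValueError("all layer widths must be positive")


def _he(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _init_small_cnn(spec: ModelSpec, rng: np.random.Generator) -> dict[str, Tensor]:
    params: dict[str, Tensor] = {}
    c_prev = 3
    for b, c in enumerate(spec.channels):
        params[f"conv{b}_w"] = Tensor(_he(rng, c, c_prev, 3, 3), requires_grad=True)
        params[f"conv{b}_b"] = Tensor(np.zeros(c), requires_grad=True)
        c_prev = c
    params["enc_w"] = Tensor(_he(rng, c_prev, spec.d_e), requires_grad=True)
    params["enc_b"] = Tensor(np.zeros(spec.d_e), requires_grad=True)
    return params


def _forward_small_cnn(params: dict[str, Tensor], x: Tensor, spec: ModelSpec) -> Tensor:
    h = x
    for b in range(len(spec.channels)):
        h = conv2d(h, params[f"conv{b}_w"], params[f"conv{b}_b"], padding=1).relu()
        h = avg_pool2(h)
    h = h.mean(axis=(2, 3))  # global average pool -> (B, C)
    return h @ params["enc_w"] + params["enc_b"]


#: encoder registry: name -> (init, forward) obeying the (B,3,S,S) -> (B, d_e) contract
ENCODERS: dict[str, tuple[Callable, Callable]] = {
    "small_cnn": (_init_small_cnn, _forward_small_cnn),
}


@dataclass
class ModelBundle:
    """Parameter state plus the forward pass of the full framework."""

    spec: ModelSpec
    params: dict[str, Tensor]

    def forward(self, rasters: np.ndarray, train: bool = True) -> tuple[Tensor, Tensor, Tensor]:
        """Map (B, 3, S, S) rasters to (r, z, logits).

        ``r`` is the unit-norm representation, ``z`` the unit-norm
        projection (contrastive space), ``logits`` the classifier output.
        The classifier reads ``r``, never ``z``, so inference is unchanged
        when the projection head is dropped.
        """
        _, fwd = ENCODERS[self.spec.encoder]
        x = Tensor(np.asarray(rasters, dtype=np.float64))
        r = normalize_rows_t(fwd(self.params, x, self.spec))
        hidden = (r @ self.params["proj_w1"] + self.params["proj_b1"]).relu()
        z = normalize_rows_t(hidden @ self.params["proj_w2"] + self.params["proj_b2"])
        logits = r @ self.params["cls_w"] + self.params["cls_b"]
        return r, z, logits

    def trainable(self, include_projection: bool = True) -> list[Tensor]:
        keys = sorted(self.params)
        if not include_projection:
            keys = [k for k in keys if not k.startswith("proj_")]
        return [self.params[k] for k in keys]

    def save(self, path: str | Path) -> None:
        """Single-file parameter state (.npz) + JSON sidecar with the spec."""
        path = Path(path)
        np.savez(path, **{k: t.data for k, t in self.params.items()})
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.spec), fh, indent=2)

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            self.spec,
            {k: Tensor(t.data.copy(), requires_grad=True) for k, t in self.params.items()},
        )


def build_model(spec: ModelSpec, seed: int) -> ModelBundle:
    """Seeded deterministic initialisation of encoder + heads."""
    if spec.encoder not in ENCODERS:
        raise ValueError(
            f"unknown encoder {spec.encoder!r}; registered: {sorted(ENCODERS)}"
        )
    rng = np.random.default_rng(seed)
    init, _ = ENCODERS[spec.encoder]
    params = init(spec, rng)
    params["proj_w1"] = Tensor(_he(rng, spec.d_e, spec.proj_hidden), requires_grad=True)
    params["proj_b1"] = Tensor(np.zeros(spec.proj_hidden), requires_grad=True)
    params["proj_w2"] = Tensor(_he(rng, spec.proj_hidden, spec.d_p), requires_grad=True)
    params["proj_b2"] = Tensor(np.zeros(spec.d_p), requires_grad=True)
    params["cls_w"] = Tensor(_he(rng, spec.d_e, spec.n_classes), requires_grad=True)
    params["cls_b"] = Tensor(np.zeros(spec.n_classes), requires_grad=True)
    return ModelBundle(spec, params)


def load_model(path: str | Path) -> ModelBundle:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        doc = json.load(fh)
    doc["channels"] = tuple(doc["channels"])
    spec = ModelSpec(**doc)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as archive:
        params = {k: Tensor(archive[k].copy(), requires_grad=True) for k in archive.files}
    return ModelBundle(spec, params)


class Adam:
    """Adaptive-moment optimizer (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
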