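"""Contrastive loss family for double-viewed batches on the unit hypersphere.

The package's central objects live here.  A batch of ``N`` source images is
expanded to ``2N`` augmented *views*; every view ``i`` acts once as an
*anchor* whose candidates are all other views ``A(i)``.  Three losses share
this geometry:

* **self-supervised (InfoNCE)** — the only positive is the sibling view
  ``j(i)`` produced from the same source image;
* **supervised contrastive (SupCon)** — every same-label view is a
  positive, ``P(i) = U(i) ∪ V(i)`` where ``U(i) = {j(i)}`` holds the
  *augmented positive* and ``V(i)`` the *same-label positives*;
* **angular margin** — similarities are re-expressed as angles
  ``θ = arccos(z_i·z_p)`` and positives are penalised with additive margins,
  ``m_u`` for the augmented positive and ``m_v`` for same-label positives,
  so that after training the sibling view sits closer to the anchor than
  other members of its class.  Negatives carry no margin.

All totals are the **mean over the 2N anchors**, so the loss scale does not
depend on batch size.  Every vectorised loss has an explicit double-loop
oracle used by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, logsumexp_rows

__all__ = [
    "MarginConfig",
    "AnchorPartition",
    "LossBreakdown",
    "make_pairing",
    "normalize_rows",
    "partition_anchors",
    "pairwise_angles",
    "self_supervised_loss",
    "supcon_loss",
    "angular_margin_loss",
    "oracle_self_supervised_loss",
    "oracle_supcon_loss",
    "oracle_angular_margin_loss",
    "cross_entropy_loss",
    "combined_loss",
]

#: inner products are clamped to [-1+EPS, 1-EPS] before arccos
EPS = 1e-7


@dataclass(frozen=True)
class MarginConfig:
    """Hyperparameters of the angular-margin loss.

    ``m_u``/``m_v`` are additive angular penalties in radians for the
    augmented and same-label positives; ``tau`` is the softmax temperature;
    ``lam`` weights the contrastive term against cross-entropy in the
    combined objective.  Defaults follow the reference protocol
    (τ=0.05, m_u=0.2, m_v=0.1, λ=1).
    """

    m_u: float = 0.2
    m_v: float = 0.1
    tau: float = 0.05
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"temperature must be positive, got {self.tau}")
        if self.m_u < 0 or self.m_v < 0:
            raise ValueError("margins must be nonnegative")
        if self.lam < 0:
            raise ValueError("combination weight must be nonnegative")


@dataclass(frozen=True)
class LossBreakdown:
    """A scalar loss plus its per-anchor decomposition."""

    total: float
    per_anchor: np.ndarray
    kind: str


@dataclass
class AnchorPartition:
    """Per-anchor index structure of a double-viewed batch.

    For anchor ``i``: ``A(i)`` is every view but ``i``; ``U(i)={j(i)}`` the
    sibling view; ``V(i)`` the other same-label views; ``P(i)=U(i)∪V(i)``.
    Boolean masks (rows = anchors) back the vectorised losses; the index
    accessors back the loop oracles.
    """

    pairing: np.ndarray
    labels: np.ndarray
    a_mask: np.ndarray = field(repr=False)
    u_mask: np.ndarray = field(repr=False)
    v_mask: np.ndarray = field(repr=False)

    @property
    def n_views(self) -> int:
        return len(self.pairing)

    @property
    def p_mask(self) -> np.ndarray:
        return self.u_mask | self.v_mask

    def A(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.a_mask[i])

    def U(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.u_mask[i])

    def V(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.v_mask[i])

    def P(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.p_mask[i])


def make_pairing(n_sources: int) -> np.ndarray:
    """Sibling map for views stacked as [first views; second views]."""
    if n_sources < 2:
        raise ValueError("need at least 2 source images per batch")
    idx = np.arange(2 * n_sources)
    return (idx + n_sources) % (2 * n_sources)


def _check_pairing(pairing: np.ndarray) -> np.ndarray:
    pairing = np.asarray(pairing, dtype=int)
    n = len(pairing)
    if n < 4 or n % 2:
        raise ValueError("a double-viewed batch needs an even number of views >= 4")
    idx = np.arange(n)
    if np.any(pairing[pairing] != idx) or np.any(pairing == idx):
        raise ValueError("pairing must be a fixed-point-free involution")
    return pairing


def normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Project each row onto the unit hypersphere (L2 normalisation)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    norms = np.linalg.norm(matrix, axis=-1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"cannot normalize all-zero row at index {zero[0]}")
    return matrix / norms[..., None]


def normalize_rows_t(matrix: Tensor) -> Tensor:
    """Differentiable row normalisation (no zero-row check: training path)."""
    sq = (matrix * matrix).sum(axis=-1, keepdims=True)
    return matrix * sq ** -0.5


def _check_batch(batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2:
        raise ValueError("projected batch must be a 2-D matrix")
    norms = np.linalg.norm(batch, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(
            f"row {bad} has norm {norms[bad]:.6f}; rows must be unit-norm"
        )
    return batch


def partition_anchors(pairing: np.ndarray, labels: np.ndarray) -> AnchorPartition:
    """Build the A/U/V index sets for every anchor of a double-viewed batch."""
    pairing = _check_pairing(pairing)
    labels = np.asarray(labels)
    if labels.shape != pairing.shape:
        raise ValueError("labels and pairing must have the same length")
    mismatch = np.flatnonzero(labels != labels[pairing])
    if mismatch.size:
        i = int(mismatch[0])
        raise ValueError(
            f"label mismatch within pair ({i}, {int(pairing[i])}): "
            f"{labels[i]!r} vs {labels[pairing[i]]!r}"
        )
    n = len(pairing)
    a_mask = ~np.eye(n, dtype=bool)
    u_mask = np.zeros((n, n), dtype=bool)
    u_mask[np.arange(n), pairing] = True
    same = labels[:, None] == labels[None, :]
    v_mask = same & a_mask & ~u_mask
    return AnchorPartition(pairing, labels, a_mask, u_mask, v_mask)


def pairwise_angles(batch: np.ndarray) -> np.ndarray:
    """Angle matrix θ(i,k) = arccos(z_i·z_k), clamped away from ±1."""
    batch = _check_batch(batch)
    g = np.clip(batch @ batch.T, -1.0 + EPS, 1.0 - EPS)
    theta = np.arccos(g)
    np.fill_diagonal(theta, 0.0)
    return theta


# --------------------------------------------------------------------------
# differentiable cores (shared by the public numpy API and the trainer)
# --------------------------------------------------------------------------
def nce_terms_t(z: Tensor, pos_mask: np.ndarray, a_mask: np.ndarray, tau: float) -> Tensor:
    """Per-anchor terms of the dot-product contrastive losses.

    term_i = logΣ_{a∈A(i)} e^{s_ia} − (1/|P(i)|) Σ_{p∈P(i)} s_ip with
    s = z zᵀ / τ; covers both the self-supervised loss (P={j(i)}) and
    SupCon (P = all same-label views).
    """
    s = (z @ z.T) * (1.0 / tau)
    lse = logsumexp_rows(s, a_mask)
    p_count = pos_mask.sum(axis=1).astype(float)
    pos_sum = (s * Tensor(pos_mask.astype(float))).sum(axis=1)
    return lse - pos_sum * Tensor(1.0 / p_count)


def angular_margin_terms_t(z: Tensor, part: AnchorPartition, cfg: MarginConfig) -> Tensor:
    """Per-anchor terms of the angular-margin loss.

    Similarities are converted to angles, the margin matrix
    ``m_u·1[a∈U(i)] + m_v·1[a∈V(i)]`` is added (zero for negatives), the
    sum is clamped at π so the penalised cosine stays monotone in θ, and
    the SupCon form is evaluated on the penalised similarities.
    """
    g = (z @ z.T).clip(-1.0 + EPS, 1.0 - EPS)
    theta = g.arccos()
    margins = cfg.m_u * part.u_mask + cfg.m_v * part.v_mask
    theta_m = (theta + Tensor(margins)).clip(0.0, np.pi)
    s = theta_m.cos() * (1.0 / cfg.tau)
    lse = logsumexp_rows(s, part.a_mask)
    p_mask = part.p_mask
    p_count = p_mask.sum(axis=1).astype(float)
    pos_sum = (s * Tensor(p_mask.astype(float))).sum(axis=1)
    return lse - pos_sum * Tensor(1.0 / p_count)


def _bundle(per_anchor: np.ndarray, kind: str) -> LossBreakdown:
    return LossBreakdown(float(np.mean(per_anchor)), per_anchor, kind)


# --------------------------------------------------------------------------
# public numpy API
# --------------------------------------------------------------------------
def self_supervised_loss(
    batch: np.ndarray, pairing: np.ndarray, tau: float
) -> LossBreakdown:
    """InfoNCE on a double-viewed batch; only the sibling view is positive."""
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    batch = _check_batch(batch)
    pairing = _check_pairing(pairing)
    n = len(pairing)
    a_mask = ~np.eye(n, dtype=bool)
    u_mask = np.zeros((n, n), dtype=bool)
    u_mask[np.arange(n), pairing] = True
    terms = nce_terms_t(Tensor(batch), u_mask, a_mask, tau).data
    return _bundle(terms, "self")


def supcon_loss(
    batch: np.ndarray, pairing: np.ndarray, labels: np.ndarray, tau: float
) -> LossBreakdown:
    """Supervised contrastive loss: all same-label views are positives."""
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    batch = _check_batch(batch)
    part = partition_anchors(pairing, labels)
    terms = nce_terms_t(Tensor(batch), part.p_mask, part.a_mask, tau).data
    return _bundle(terms, "supcon")


def angular_margin_loss(
    batch: np.ndarray,
    pairing: np.ndarray,
    labels: np.ndarray,
    cfg: MarginConfig,
) -> LossBreakdown:
    """SupCon with additive angular margins on the positives."""
    batch = _check_batch(batch)
    part = partition_anchors(pairing, labels)
    terms = angular_margin_terms_t(Tensor(batch), part, cfg).data
    return _bundle(terms, "angular_margin")


# --------------------------------------------------------------------------
# brute-force oracles: literal nested loops, no vectorisation
# --------------------------------------------------------------------------
def oracle_self_supervised_loss(
    batch: np.ndarray, pairing: np.ndarray, tau: float
) -> LossBreakdown:
    """Loop transcription of the self-supervised loss (test oracle)."""
    batch = _check_batch(batch)
    pairing = _check_pairing(pairing)
    n = len(pairing)
    terms = []
    for i in range(n):
        denom = 0.0
        for a in range(n):
            if a != i:
                denom += np.exp(batch[i] @ batch[a] / tau)
        num = np.exp(batch[i] @ batch[pairing[i]] / tau)
        terms.append(-np.log(num / denom))
    return _bundle(np.array(terms), "self")


def oracle_supcon_loss(
    batch: np.ndarray, pairing: np.ndarray, labels: np.ndarray, tau: float
) -> LossBreakdown:
    """Loop transcription of SupCon (test oracle)."""
    batch = _check_batch(batch)
    part = partition_anchors(pairing, labels)
    terms = []
    for i in range(part.n_views):
        denom = 0.0
        for a in part.A(i):
            denom += np.exp(batch[i] @ batch[a] / tau)
        acc = 0.0
        for p in part.P(i):
            acc += np.log(np.exp(batch[i] @ batch[p] / tau) / denom)
        terms.append(-acc / len(part.P(i)))
    return _bundle(np.array(terms), "supcon")


def oracle_angular_margin_loss(
    batch: np.ndarray,
    pairing: np.ndarray,
    labels: np.ndarray,
    cfg: MarginConfig,
) -> LossBreakdown:
    """Loop transcription of the angular-margin loss (test oracle).

    Enumerates every anchor, positive and candidate literally; intended for
    small batches (readability, not speed).
    """
    batch = _check_batch(batch)
    part = partition_anchors(pairing, labels)

    def penalised(i: int, a: int) -> float:
        theta = np.arccos(np.clip(batch[i] @ batch[a], -1 + EPS, 1 - EPS))
        if a == part.pairing[i]:
            theta += cfg.m_u
        elif part.labels[a] == part.labels[i]:
            theta += cfg.m_v
        return np.exp(np.cos(min(theta, np.pi)) / cfg.tau)

    terms = []
    for i in range(part.n_views):
        denom = 0.0
        for a in part.A(i):
            denom += penalised(i, int(a))
        acc = 0.0
        for p in part.P(i):
            acc += np.log(penalised(i, int(p)) / denom)
        terms.append(-acc / len(part.P(i)))
    return _bundle(np.array(terms), "angular_margin")


# --------------------------------------------------------------------------
# cross-entropy and the combined objective
# --------------------------------------------------------------------------
def cross_entropy_loss(scores: np.ndarray, labels: np.ndarray) -> LossBreakdown:
    """Cross-entropy from probabilities.

    ``scores`` is either a (n, k) matrix of class probabilities (rows sum to
    one) or a length-n vector of positive-class probabilities for the binary
    task.  The total is the mean over samples.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if scores.ndim == 1:
        if labels.shape != scores.shape:
            raise ValueError("labels/scores length mismatch")
        p = np.where(labels == 1, scores, 1.0 - scores)
    else:
        if len(labels) != scores.shape[0]:
            raise ValueError("labels/scores length mismatch")
        rowsum = scores.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")
        p = scores[np.arange(len(labels)), labels]
    with np.errstate(divide="ignore"):
        terms = -np.log(p)
    return _bundle(terms, "cross_entropy")


def combined_loss(ce: LossBreakdown, am: LossBreakdown, lam: float) -> LossBreakdown:
    """Joint objective L = L_ce + λ·L_contrastive."""
    if lam < 0:
        raise ValueError("combination weight must be nonnegative")
    total = ce.total + lam * am.total
    return LossBreakdown(total, np.array([total]), "combined")
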