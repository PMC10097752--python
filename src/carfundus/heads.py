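"""Two-stage classifier scaffold: linear finding heads over pooled features
and linear disease heads over the concatenation of all pooled finding features.

The finding stage produces, per finding f, a spatial feature map ``g_f(x)`` of
shape (C, H', W') whose global average pool ``z_f`` feeds a linear head
(w_f, b_f); the disease stage scores sigma(sum_f v_{d,f}Â·z_f + c_d).  Only the
linear heads are trained here; the feature extractor is supplied separately
(see :mod:`carfundus.encoder`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._util import as_vector, sigmoid


@dataclass
class FindingHead:
    """Linear classifier for one finding over its pooled feature vector."""

    name: str
    weight: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weight = as_vector(self.weight, f"weight of finding head {self.name!r}")
        self.bias = float(self.bias)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weight))

    @property
    def unit_weight(self) -> np.ndarray:
        n = self.norm
        if n == 0:
            raise DegenerateHeadError(f"finding head {self.name!r} has zero-norm weight")
        return self.weight / n


@dataclass
class DiseaseHead:
    """Linear classifier for one disease over concatenated pooled finding features.

    ``blocks[f]`` is the weight vector v_{d,f} applied to finding f's pooled
    features; ``intercept`` is c_d.
    """

    name: str
    blocks: list[np.ndarray]
    intercept: float

    def __post_init__(self) -> None:
        self.blocks = [as_vector(b, f"block {i} of disease head {self.name!r}")
                       for i, b in enumerate(self.blocks)]
        lengths = {b.shape[0] for b in self.blocks}
        if len(lengths) > 1:
            raise ValueError(f"disease head {self.name!r} has blocks of unequal length {lengths}")
        self.intercept = float(self.intercept)

    @property
    def n_findings(self) -> int:
        return len(self.blocks)

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.blocks)


class DegenerateHeadError(ValueError):
    """Raised when a finding head's weight vector has zero norm."""


@dataclass
class EncoderSpec:
    """Shape contract for the lightweight convolutional encoder."""

    input_size: int = 64
    shared_depth: int = 1
    branch_depth: int = 1
    channels: int = 8

    def __post_init__(self) -> None:
        for name in ("input_size", "shared_depth", "branch_depth", "channels"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"EncoderSpec.{name} must be a positive integer, got {v!r}")


@dataclass
class LatentFeatures:
    """Per-finding spatial feature maps g_f(x) and their pooled vectors z_f."""

    per_finding_maps: list[np.ndarray]
    pooled: list[np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.per_finding_maps = [np.asarray(m, dtype=float) for m in self.per_finding_maps]
        for m in self.per_finding_maps:
            if m.ndim != 3:
                raise ValueError(f"feature maps must be C x H' x W', got shape {m.shape}")
        if self.pooled is None:
            self.pooled = [pool_features(m) for m in self.per_finding_maps]
        else:
            self.pooled = [as_vector(p, "pooled") for p in self.pooled]
            for m, p in zip(self.per_finding_maps, self.pooled):
                if not np.allclose(pool_features(m), p, atol=1e-6):
                    raise ValueError("pooled vector does not match spatial mean of its map")


@dataclass
class ModelBundle:
    """A full two-stage model: one head per finding, one per disease."""

    findings: list[FindingHead]
    diseases: list[DiseaseHead]

    def __post_init__(self) -> None:
        for d in self.diseases:
            if d.n_findings != len(self.findings):
                raise ValueError(
                    f"disease head {d.name!r} has {d.n_findings} blocks "
                    f"but the bundle declares {len(self.findings)} findings"
                )

    @property
    def finding_names(self) -> list[str]:
        return [h.name for h in self.findings]

    @property
    def disease_names(self) -> list[str]:
        return [h.name for h in self.diseases]

    @property
    def channels(self) -> int:
        return int(self.findings[0].weight.shape[0])

    def finding_index(self, name: str) -> int:
        try:
            return self.finding_names.index(name)
        except ValueError:
            raise KeyError(f"unknown finding {name!r}; known: {self.finding_names}") from None

    def finding_scores(self, pooled_all: Sequence[np.ndarray]) -> np.ndarray:
        return np.array([finding_score(h, z) for h, z in zip(self.findings, pooled_all)])

    def disease_scores(self, pooled_all: Sequence[np.ndarray]) -> np.ndarray:
        return np.array([disease_score(h, pooled_all) for h in self.diseases])

    def normalized(self) -> "ModelBundle":
        """Rescale every finding head to unit weight norm (bias preserved).

        Under this convention the pooled feature's projection coefficient onto
        w_f equals logit(finding score) - b_f exactly, matching the textbook
        form of the decomposition.  Finding probabilities change by a logit
        rescaling; disease heads are untouched.
        """
        return ModelBundle(
            findings=[FindingHead(h.name, h.unit_weight, h.bias) for h in self.findings],
            diseases=self.diseases,
        )


def pool_features(maps: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel spatial mean of a C x H' x W' map."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError(f"expected a C x H' x W' tensor, got shape {maps.shape}")
    c, h, w = maps.shape
    if h * w < 1:
        raise ValueError("empty spatial domain: H' * W' must be >= 1")
    return maps.mean(axis=(1, 2))


def finding_logit(head: FindingHead, pooled: np.ndarray) -> float:
    pooled = as_vector(pooled, "pooled")
    if pooled.shape != head.weight.shape:
        raise ValueError(
            f"dimension mismatch for finding {head.name!r}: "
            f"weight {head.weight.shape} vs pooled {pooled.shape}"
        )
    return float(head.weight @ pooled + head.bias)


def finding_score(head: FindingHead, pooled: np.ndarray) -> float:
    """sigma(w_f . z_f + b_f)."""
    return float(sigmoid(finding_logit(head, pooled)))


def disease_linear(head: DiseaseHead, pooled_all: Sequence[np.ndarray]) -> float:
    if len(pooled_all) != head.n_findings:
        raise ValueError(
            f"disease {head.name!r} expects {head.n_findings} pooled vectors, "
            f"got {len(pooled_all)}"
        )
    total = head.intercept
    for block, z in zip(head.blocks, pooled_all):
        z = as_vector(z, "pooled")
        if z.shape != block.shape:
            raise ValueError(f"dimension mismatch in disease {head.name!r}")
        total += float(block @ z)
    return float(total)


def disease_score(head: DiseaseHead, pooled_all: Sequence[np.ndarray]) -> float:
    """sigma(sum_f v_{d,f} . z_f + c_d)."""
    return float(sigmoid(disease_linear(head, pooled_all)))


# ---------------------------------------------------------------------------
# Head training: regularized logistic regression by deterministic full-batch
# gradient descent with Armijo backtracking (loss provably non-increasing).
# ---------------------------------------------------------------------------

def _bce_loss(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, l2: float) -> float:
    z = X @ w + b
    # log(1+exp(-z)) for y=1, log(1+exp(z)) for y=0, soft targets interpolate
    loss = np.mean(np.logaddexp(0.0, z) - y * z)
    return float(loss + l2 * (w @ w + b * b))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 5e-4,
    lr: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize mean BCE + l2*||params||^2; returns (weights, bias, loss history).

    Targets may be soft (any values in [0, 1]).  Deterministic: full-batch
    descent with backtracking line search, no randomness.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) and y (n,)")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must lie in [0, 1]")
    if y.min() == y.max() and y.min() in (0.0, 1.0):
        warnings.warn(
            f"all targets equal {y.min():g}: fit is intercept-dominated",
            stacklevel=2,
        )
    n, p = X.shape
    w = np.zeros(p)
    b = 0.0
    losses = [_bce_loss(X, y, w, b, l2)]
    step = lr
    for _ in range(max_iter):
        z = X @ w + b
        r = sigmoid(z) - y
        gw = X.T @ r / n + 2.0 * l2 * w
        gb = float(np.mean(r) + 2.0 * l2 * b)
        gnorm2 = float(gw @ gw + gb * gb)
        if gnorm2 < 1e-18:
            break
        # Armijo backtracking
        step = min(step * 2.0, 1e4)
        while True:
            w_new = w - step * gw
            b_new = b - step * gb
            new_loss = _bce_loss(X, y, w_new, b_new, l2)
            if new_loss <= losses[-1] - 1e-4 * step * gnorm2 or step < 1e-12:
                break
            step *= 0.5
        w, b = w_new, b_new
        losses.append(new_loss)
        if abs(losses[-2] - losses[-1]) < tol * max(1.0, abs(losses[-2])):
            break
    return w, b, losses


def train_finding_heads(
    pooled: np.ndarray,
    targets: np.ndarray,
    names: Sequence[str],
    l2: float = 5e-4,
    **fit_kwargs,
) -> tuple[list[FindingHead], list[list[float]]]:
    """Fit one finding head per label on its own pooled features.

    ``pooled`` has shape (n, F, C); ``targets`` (n, F) with values in [0, 1]
    (fused posteriors are valid soft targets).
    """
    pooled = np.asarray(pooled, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n, F, C = pooled.shape
    heads, histories = [], []
    for f, name in enumerate(names):
        w, b, losses = fit_logistic(pooled[:, f, :], targets[:, f], l2=l2, **fit_kwargs)
        heads.append(FindingHead(name, w, b))
        histories.append(losses)
    return heads, histories


def train_disease_heads(
    pooled: np.ndarray,
    targets: np.ndarray,
    names: Sequence[str],
    l2: float = 5e-4,
    **fit_kwargs,
) -> tuple[list[DiseaseHead], list[list[float]]]:
    """Fit one disease head per label on concatenated pooled finding features.

    ``pooled`` has shape (n, F, C) — F pooled vectors per image; ``targets``
    (n, D).  Returns the heads and per-head loss histories (non-increasing).
    """
    pooled = np.asarray(pooled, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if pooled.ndim != 3:
        raise ValueError("pooled must be (n, F, C)")
    if targets.ndim == 1:
        targets = targets[:, None]
    n, F, C = pooled.shape
    X = pooled.reshape(n, F * C)
    heads, histories = [], []
    for d, name in enumerate(names):
        w, b, losses = fit_logistic(X, targets[:, d], l2=l2, **fit_kwargs)
        heads.append(DiseaseHead(name, [w[f * C:(f + 1) * C] for f in range(F)], b))
        histories.append(losses)
    return heads, histories


def balanced_batches(
    labels: np.ndarray,
    batch_size: int,
    seed: int,
) -> Iterator[np.ndarray]:
    """Endless stream of index batches with expected positive fraction 1/2.

    Each slot independently picks the positive class with probability 0.5 and
    then an example uniformly within that class, so every example retains a
    nonzero sampling probability regardless of prevalence.
    """
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        raise ValueError("cannot balance batches: no positive examples present")
    if neg.size == 0:
        raise ValueError("cannot balance batches: no negative examples present")
    rng = np.random.default_rng(seed)
    while True:
        take_pos = rng.random(batch_size) < 0.5
        idx = np.where(
            take_pos,
            pos[rng.integers(0, pos.size, size=batch_size)],
            neg[rng.integers(0, neg.size, size=batch_size)],
        )
        yield idx
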