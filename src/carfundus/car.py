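"""Counterfactual attribution ratios (CAR) for two-stage classifiers.

Given a finding head (w_f, b_f) and a disease head with per-finding blocks
v_{d,f}, the pooled finding feature decomposes into a component along w_f and
an orthogonal remainder.  Replacing the parallel component so the finding
score becomes a small epsilon yields a counterfactual latent "as if the
finding were absent"; the ratio of the disease odds to the counterfactual
odds is the instance-dependent attribution ratio

    R_ICAR(f, d; x) = exp((logit(yhat_f) - logit(eps)) * kappa(f, d)),

with coupling kappa(f, d) = v_{d,f} . w_f / ||w_f||^2 (equal to v_{d,f} . w_f
for unit-norm heads).  Replacing yhat_f with 1 - eps gives the
instance-independent CAR

    R_CAR(f, d) = exp((logit(1 - eps) - logit(eps)) * kappa(f, d)),

directly comparable to the odds ratio human experts exhibit for the same
finding-disease pair.  All identities here hold exactly for raw (non-unit)
heads; ``ModelBundle.normalized()`` gives the unit-norm convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import as_vector, logit, sigmoid
from .heads import (
    DegenerateHeadError,
    DiseaseHead,
    FindingHead,
    ModelBundle,
    disease_linear,
    disease_score,
    finding_score,
    pool_features,
)

#: display threshold for "relevant" findings: the natural constant e
DISPLAY_THRESHOLD = math.e

#: default epsilon when no benign validation predictions are available
#: (midpoint of the permitted interval (0, 1/100))
DEFAULT_EPSILON = 0.005


@dataclass
class Decomposition:
    """Pooled feature split into its component along w_f and the remainder."""

    parallel_coeff: float
    direction: np.ndarray
    orthogonal: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.parallel_coeff * self.direction + self.orthogonal


@dataclass
class EpsilonPolicy:
    """How the counterfactual confidence epsilon is chosen.

    mode "fixed" uses ``value``; mode "benign_percentile" takes the
    ``percentile``-th ordered statistic of finding predictions on benign
    validation cases (nearest rank), clipped into the open interval
    (0, 1/100).
    """

    mode: str = "fixed"
    value: float = DEFAULT_EPSILON
    percentile: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "benign_percentile"):
            raise ValueError(f"unknown epsilon mode {self.mode!r}")
        if self.mode == "fixed" and not (0.0 < self.value < 0.01):
            raise ValueError("epsilon must lie strictly inside (0, 1/100)")


@dataclass
class CARMatrix:
    """F x D grid of counterfactual attribution ratios."""

    values: np.ndarray
    finding_names: list[str]
    disease_names: list[str]
    epsilon: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.finding_names, columns=self.disease_names)

    def log_values(self) -> np.ndarray:
        return np.log(self.values)


@dataclass
class AttributionMap:
    """Spatial attribution of finding f to disease d: a coupling-scaled CAM."""

    grid: np.ndarray
    finding: str
    disease: str

    def upsample(self, size: int) -> np.ndarray:
        """Bilinear upsampling for overlay rendering (raw values preserved)."""
        from PIL import Image

        img = Image.fromarray(self.grid.astype(np.float32), mode="F")
        return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=float)


def decompose(pooled: np.ndarray, head: FindingHead) -> Decomposition:
    """Split a pooled feature into parallel + orthogonal parts w.r.t. w_f."""
    pooled = as_vector(pooled, "pooled")
    direction = head.unit_weight  # raises DegenerateHeadError on zero norm
    coeff = float(direction @ pooled)
    orthogonal = pooled - coeff * direction
    return Decomposition(parallel_coeff=coeff, direction=direction, orthogonal=orthogonal)


def odds(disease_pred: float) -> float:
    """Odds yhat_d / (1 - yhat_d); equals exp(linear disease score)."""
    p = float(disease_pred)
    if not (0.0 < p < 1.0):
        raise ValueError(f"odds undefined for prediction {p}; must be inside (0, 1)")
    return p / (1.0 - p)


def coupling(head_f: FindingHead, head_d: DiseaseHead, f: int) -> float:
    """kappa(f, d) = v_{d,f} . w_f / ||w_f||^2 (v . w for unit-norm heads)."""
    n = head_f.norm
    if n == 0:
        raise DegenerateHeadError(f"finding head {head_f.name!r} has zero-norm weight")
    return float(head_d.blocks[f] @ head_f.weight) / (n * n)


def counterfactual_latent(dec: Decomposition, head: FindingHead, eps: float) -> np.ndarray:
    """Pooled feature with the parallel part moved so the finding score is eps."""
    if not (0.0 < eps < 1.0):
        raise ValueError("eps must lie strictly inside (0, 1)")
    coeff = (logit(eps, clip=False) - head.bias) / head.norm
    return coeff * dec.direction + dec.orthogonal


def counterfactual_odds(
    latents: Sequence[np.ndarray],
    head_d: DiseaseHead,
    head_f: FindingHead,
    f: int,
    eps: float,
) -> float:
    """Odds after suppressing finding f's evidence to score eps: C(f, d; x)."""
    dec = decompose(latents[f], head_f)
    z_cf = counterfactual_latent(dec, head_f, eps)
    modified = list(latents)
    modified[f] = z_cf
    return float(np.exp(disease_linear(head_d, modified)))


def icar(finding_pred: float, eps: float, coupling_value: float) -> float:
    """Closed-form instance-dependent CAR: exp((logit(yhat_f) - logit(eps)) * kappa)."""
    lf = logit(finding_pred, clip=False)
    le = logit(eps, clip=False)
    if not (np.isfinite(lf) and np.isfinite(le)):
        raise ValueError("non-finite logits in I-CAR")
    return float(np.exp((lf - le) * coupling_value))


def car(head_f: FindingHead, head_d: DiseaseHead, f: int, eps: float = DEFAULT_EPSILON) -> float:
    """Instance-independent CAR: exp((logit(1-eps) - logit(eps)) * kappa).

    By logit antisymmetry this equals exp(-2 * logit(eps) * kappa).
    """
    if not (0.0 < eps < 0.01):
        raise ValueError("eps must lie strictly inside (0, 1/100)")
    kappa = coupling(head_f, head_d, f)
    return float(np.exp(-2.0 * logit(eps, clip=False) * kappa))


def car_matrix(model: ModelBundle, eps: float = DEFAULT_EPSILON) -> CARMatrix:
    """All F x D counterfactual attribution ratios (instance-independent)."""
    values = np.empty((len(model.findings), len(model.diseases)))
    for f, hf in enumerate(model.findings):
        for d, hd in enumerate(model.diseases):
            values[f, d] = car(hf, hd, f, eps)
    return CARMatrix(values, model.finding_names, model.disease_names, eps)


def instance_icars(
    latents: Sequence[np.ndarray],
    model: ModelBundle,
    eps: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """F x D grid of instance-dependent CARs for one image's pooled features."""
    out = np.empty((len(model.findings), len(model.diseases)))
    for f, hf in enumerate(model.findings):
        yf = finding_score(hf, latents[f])
        for d, hd in enumerate(model.diseases):
            out[f, d] = icar(yf, eps, coupling(hf, hd, f))
    return out


def select_epsilon(benign_preds: Sequence[float] | None, policy: EpsilonPolicy) -> float:
    """Choose epsilon per policy; percentile mode uses the nearest-rank statistic."""
    if policy.mode == "fixed":
        return policy.value
    if benign_preds is None or len(benign_preds) == 0:
        raise ValueError(
            "benign_percentile mode requires benign predictions; "
            "use EpsilonPolicy(mode='fixed') if none are available"
        )
    preds = np.sort(np.asarray(benign_preds, dtype=float))
    if preds.size < 20:
        warnings.warn(
            f"only {preds.size} benign predictions; the percentile estimate is noisy",
            stacklevel=2,
        )
    rank = max(1, int(math.ceil(policy.percentile / 100.0 * preds.size)))
    value = float(preds[rank - 1])
    hi = np.nextafter(0.01, 0.0)
    lo = 1e-9
    if value >= 0.01 or value <= 0.0:
        warnings.warn(
            f"benign percentile {value:g} outside (0, 1/100); clipped",
            stacklevel=2,
        )
    return float(min(max(value, lo), hi))


def attribution_map(
    latent_map: np.ndarray,
    head_f: FindingHead,
    head_d: DiseaseHead,
    f: int,
) -> AttributionMap:
    """A(f, d; x) = (v_{d,f} . w_f/||w_f||) * (w_f^T g_f(x)) as an H' x W' map.

    Because the spatial mean of w_f^T g_f(x) is w_f^T z_f = logit(yhat_f) - b_f,
    the map's spatial mean equals (v . w_hat) * (logit(yhat_f) - b_f) for any
    weight norm.
    """
    latent_map = np.asarray(latent_map, dtype=float)
    if latent_map.ndim != 3:
        raise ValueError("latent_map must be C x H' x W'")
    w_hat = head_f.unit_weight
    scale = float(head_d.blocks[f] @ w_hat)
    grid = scale * np.einsum("c,chw->hw", head_f.weight, latent_map)
    return AttributionMap(grid=grid, finding=head_f.name, disease=head_d.name)


def top_findings(
    icars: Sequence[float],
    finding_names: Sequence[str],
    threshold: float = DISPLAY_THRESHOLD,
    k: int = 3,
) -> list[tuple[str, float]]:
    """Findings whose I-CAR exceeds the display threshold, strongest first, top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = [(name, float(v)) for name, v in zip(finding_names, icars) if v > threshold]
    pairs.sort(key=lambda t: -t[1])
    return pairs[:k]


def interactive_adjust(
    latents: Sequence[np.ndarray],
    model: ModelBundle,
    overrides: Mapping[str, float],
) -> np.ndarray:
    """Re-evaluate all disease heads after overriding finding scores.

    For each overridden finding the parallel component of its pooled feature
    is moved so the finding score equals the requested probability; the
    orthogonal component (lesion appearance unrelated to the head's decision
    axis) is untouched.  No encoder pass is needed, so re-evaluation is
    essentially free.
    """
    latents = [as_vector(z, "pooled") for z in latents]
    modified = list(latents)
    for name, p in overrides.items():
        if not (0.0 < float(p) < 1.0):
            raise ValueError(f"override for {name!r} must be inside (0, 1), got {p}")
        f = model.finding_index(name)
        head = model.findings[f]
        dec = decompose(latents[f], head)
        modified[f] = counterfactual_latent(dec, head, float(p))
    return np.array([disease_score(hd, modified) for hd in model.diseases])


def explain_instance(
    latents: Sequence[np.ndarray],
    model: ModelBundle,
    eps: float = DEFAULT_EPSILON,
    threshold: float = DISPLAY_THRESHOLD,
    k: int = 3,
) -> dict:
    """Per-image explanation: scores, I-CAR grid, and top findings per disease."""
    finding_scores = model.finding_scores(latents)
    disease_scores = model.disease_scores(latents)
    grid = instance_icars(latents, model, eps)
    tops = {
        dname: top_findings(grid[:, d], model.finding_names, threshold, k)
        for d, dname in enumerate(model.disease_names)
    }
    return {
        "finding_scores": dict(zip(model.finding_names, finding_scores.tolist())),
        "disease_scores": dict(zip(model.disease_names, disease_scores.tolist())),
        "icar": grid,
        "top_findings": tops,
        "epsilon": eps,
        "threshold": threshold,
    }
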