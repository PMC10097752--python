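"""Screening-classifier evaluation: AUROC, exact binomial (Clopper-Pearson)
intervals, operating-point selection, and the cosine-distance analysis used
to pick the encoder branch point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta, norm
from sklearn.metrics import roc_auc_score


def _check_two_class(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUROC with its DeLong (1988) asymptotic confidence interval.

    Returns (auc, lower, upper).  Uses the placement-value formulation: the
    variance is var(V10)/m + var(V01)/n for m positives and n negatives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # placement values via pairwise comparison (fine at evaluation scale)
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # per-positive
    v01 = cmp.mean(axis=0)  # per-negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = float(norm.ppf(1.0 - alpha / 2.0))
    half = z * np.sqrt(var)
    return auc, float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


@dataclass
class OperatingPoint:
    """A decision threshold with its sensitivity/specificity profile."""

    threshold: float
    sensitivity: float
    specificity: float

    @property
    def harmonic_mean(self) -> float:
        s = self.sensitivity + self.specificity
        return 0.0 if s == 0 else 2.0 * self.sensitivity * self.specificity / s


def _sens_spec(scores, labels, threshold) -> tuple[float, float]:
    pred = scores >= threshold
    pos = labels == 1
    sens = float(np.mean(pred[pos])) if pos.any() else 0.0
    spec = float(np.mean(~pred[~pos])) if (~pos).any() else 0.0
    return sens, spec


def choose_operating_point(
    scores: Sequence[float],
    labels: Sequence[int],
    policy: str = "max_harmonic_mean",
    target: float = 0.9,
) -> OperatingPoint:
    """Select a decision threshold for a screening classifier.

    policy "max_harmonic_mean" scans candidate thresholds at midpoints
    between adjacent distinct scores (plus outer sentinels) and returns the
    maximizer of 2*sens*spec/(sens+spec), breaking ties toward higher
    specificity.  policy "target_sensitivity" returns the largest threshold
    whose sensitivity is at least ``target`` (screening at a sensitivity
    floor, used when positives are scarce).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    if policy == "max_harmonic_mean":
        best = None
        for t in candidates:
            sens, spec = _sens_spec(scores, labels, t)
            op = OperatingPoint(float(t), sens, spec)
            if best is None or op.harmonic_mean > best.harmonic_mean + 1e-15 or (
                abs(op.harmonic_mean - best.harmonic_mean) <= 1e-15
                and op.specificity > best.specificity
            ):
                best = op
        return best
    if policy == "target_sensitivity":
        feasible = []
        for t in candidates:
            sens, spec = _sens_spec(scores, labels, t)
            if sens >= target:
                feasible.append(OperatingPoint(float(t), sens, spec))
        if not feasible:
            warnings.warn(f"target sensitivity {target} unreachable; "
                          "returning the minimum threshold", stacklevel=2)
            t = float(candidates[0])
            sens, spec = _sens_spec(scores, labels, t)
            return OperatingPoint(t, sens, spec)
        return max(feasible, key=lambda op: op.threshold)
    raise ValueError(f"unknown policy {policy!r}")


def roc_points(scores, labels) -> np.ndarray:
    """(threshold, sensitivity, specificity) rows over all candidate thresholds."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_class(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    rows = []
    for t in candidates:
        sens, spec = _sens_spec(scores, labels, t)
        rows.append((float(t), sens, spec))
    return np.asarray(rows)


def mean_pairwise_cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - mean cosine similarity over all cross pairs of two vector sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    for name, norms in (("first", na), ("second", nb)):
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero feature vector at index {bad[0]} of the {name} set")
    sims = (a / na[:, None]) @ (b / nb[:, None]).T
    return float(1.0 - sims.mean())


def cosine_branch_analysis(
    layer_sets: Mapping[str, Mapping[str, np.ndarray]],
    margin: float = 0.0,
) -> dict:
    """Mean cosine distance between finding pairs at each encoder depth.

    ``layer_sets`` maps layer name -> {finding name -> (n_f, C) pooled feature
    array}.  Per layer, the statistic is the mean over all ordered finding
    pairs (i != j) of the mean pairwise cosine distance between their images'
    features.  The suggested branch point is the first layer whose mean
    distance exceeds its predecessor's by more than ``margin`` — features are
    still shared below it and diverge above it.
    """
    layers = list(layer_sets)
    means = {}
    for layer in layers:
        groups = layer_sets[layer]
        names = list(groups)
        if len(names) < 2:
            raise ValueError("need at least two findings per layer")
        dists = [
            mean_pairwise_cosine_distance(np.atleast_2d(groups[fi]), np.atleast_2d(groups[fj]))
            for i, fi in enumerate(names)
            for j, fj in enumerate(names)
            if i != j
        ]
        means[layer] = float(np.mean(dists))
    branch = None
    for prev, cur in zip(layers[:-1], layers[1:]):
        if means[cur] > means[prev] + margin:
            branch = cur
            break
    return {"mean_distance": means, "suggested_branch_layer": branch}
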