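"""Multi-reader label fusion: Naive Bayes posteriors with EM-estimated reader
profiles (a two-class Dawid-Skene model), severity recoding, and the
conservative majority/unanimity reference-standard rule.

Readers annotate each image independently, so conditional on the true label
their marks are independent Bernoulli draws governed by per-reader
sensitivity and specificity.  The posterior that an image is truly positive
given the panel of marks is the training target (a soft label); reader
profiles and the label prior are estimated by expectation-maximization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ReaderProfile:
    """Per-reader operating characteristics for one label."""

    reader: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for field in ("sensitivity", "specificity"):
            v = float(getattr(self, field))
            if not (0.0 < v < 1.0):
                raise ValueError(f"{field} of reader {self.reader!r} must be inside (0, 1)")
            setattr(self, field, v)


@dataclass
class LabelPrior:
    """Prevalence Pr(Y = 1) of one label."""

    label: str
    prevalence: float

    def __post_init__(self) -> None:
        self.prevalence = float(self.prevalence)
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence of {self.label!r} must be inside (0, 1)")


def _likelihoods(marks: np.ndarray, sens: np.ndarray, spec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pr(marks | Y=1) and Pr(marks | Y=0), product over readers (rows: images)."""
    like_pos = np.prod(np.where(marks == 1, sens, 1.0 - sens), axis=-1)
    like_neg = np.prod(np.where(marks == 1, 1.0 - spec, spec), axis=-1)
    return like_pos, like_neg


def naive_bayes_posterior(
    marks: Sequence[int],
    profiles: Sequence[ReaderProfile],
    prior: LabelPrior,
) -> float:
    """Pr(Y = 1 | reader marks) under conditional independence of readers."""
    marks_arr = np.asarray(marks, dtype=int)
    if marks_arr.ndim != 1 or len(profiles) != marks_arr.size:
        raise ValueError("need exactly one profile per mark")
    if not np.isin(marks_arr, (0, 1)).all():
        raise ValueError("marks must be binary")
    sens = np.array([p.sensitivity for p in profiles])
    spec = np.array([p.specificity for p in profiles])
    like_pos, like_neg = _likelihoods(marks_arr, sens, spec)
    num = like_pos * prior.prevalence
    den = num + like_neg * (1.0 - prior.prevalence)
    return float(num / den)


def panel_matrix(panel: pd.DataFrame, label: str) -> tuple[np.ndarray, list, list]:
    """Pivot a long panel (image_id, reader_id, label columns) to images x readers."""
    if label not in panel.columns:
        raise KeyError(f"label {label!r} not in panel columns {list(panel.columns)}")
    wide = panel.pivot(index="image_id", columns="reader_id", values=label)
    if wide.isna().any().any():
        raise ValueError("panel is incomplete: every image needs a mark from every reader")
    return wide.to_numpy(dtype=int), list(wide.index), list(wide.columns)


@dataclass
class EMResult:
    profiles: list[ReaderProfile]
    prior: LabelPrior
    posteriors: pd.Series  # indexed by image_id
    log_likelihoods: list[float]
    converged: bool


def em_estimate(
    panel: pd.DataFrame,
    label: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Fit reader sensitivities/specificities and the label prior by EM.

    E-step: Naive Bayes posterior per image under current parameters.
    M-step: posterior-weighted empirical sensitivity, specificity, prevalence.
    Initialization from majority-vote pseudo-labels (deterministic, avoids
    label switching); the observed-data log-likelihood is non-decreasing.
    """
    marks, image_ids, reader_ids = panel_matrix(panel, label)
    n, n_readers = marks.shape
    if n < 50:
        warnings.warn(f"only {n} images: EM estimates will be unstable", stacklevel=2)

    clip = 1e-6
    majority = (marks.mean(axis=1) > 0.5).astype(float)
    q = np.clip(majority, clip, 1.0 - clip)

    def m_step(q):
        wpos = q.sum()
        wneg = (1.0 - q).sum()
        sens = np.clip((q[:, None] * marks).sum(axis=0) / wpos, clip, 1.0 - clip)
        spec = np.clip(((1.0 - q)[:, None] * (1 - marks)).sum(axis=0) / wneg, clip, 1.0 - clip)
        prev = float(np.clip(wpos / n, clip, 1.0 - clip))
        return sens, spec, prev

    sens, spec, prev = m_step(q)
    log_liks: list[float] = []
    converged = False
    for _ in range(max_iter):
        like_pos, like_neg = _likelihoods(marks, sens, spec)
        num = like_pos * prev
        den = num + like_neg * (1.0 - prev)
        q = num / den
        log_liks.append(float(np.log(den).sum()))
        new_sens, new_spec, new_prev = m_step(q)
        delta = max(
            float(np.abs(new_sens - sens).max()),
            float(np.abs(new_spec - spec).max()),
            abs(new_prev - prev),
        )
        sens, spec, prev = new_sens, new_spec, new_prev
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations", stacklevel=2)

    # label-switching guard: if readers look collectively worse than chance,
    # the mirrored solution (truth flipped) is the intended one
    if float(np.mean(sens + spec)) < 1.0:
        warnings.warn("degenerate EM solution re-anchored by flipping the latent class",
                      stacklevel=2)
        q = 1.0 - q
        sens, spec, prev = m_step(q)
        like_pos, like_neg = _likelihoods(marks, sens, spec)
        num = like_pos * prev
        q = num / (num + like_neg * (1.0 - prev))

    profiles = [ReaderProfile(str(r), float(s), float(c))
                for r, s, c in zip(reader_ids, sens, spec)]
    return EMResult(
        profiles=profiles,
        prior=LabelPrior(label, prev),
        posteriors=pd.Series(q, index=pd.Index(image_ids, name="image_id"), name=label),
        log_likelihoods=log_liks,
        converged=converged,
    )


def severity_recode(
    ordered_labels: Sequence[str],
    reader_categories: Sequence[str],
    none_category: str = "none",
) -> dict[str, tuple[int, ...]]:
    """Expand per-reader ordinal severity calls into per-label binary marks.

    ``ordered_labels`` runs from least to most severe.  A reader marking
    severity level s counts as positive for every label at severity <= s:
    e.g. with labels (DR, referable DR), calls (DR, referable DR, none) give
    marks (1, 1, 0) for DR and (0, 1, 0) for referable DR.
    """
    order = {lab: i for i, lab in enumerate(ordered_labels)}
    if none_category in order:
        raise ValueError(f"{none_category!r} cannot also be a severity label")
    marks: dict[str, list[int]] = {lab: [] for lab in ordered_labels}
    for cat in reader_categories:
        if cat == none_category:
            level = -1
        elif cat in order:
            level = order[cat]
        else:
            raise ValueError(f"unknown category {cat!r}; expected one of "
                             f"{[none_category, *ordered_labels]}")
        for lab, i in order.items():
            marks[lab].append(1 if i <= level else 0)
    return {lab: tuple(v) for lab, v in marks.items()}


def reference_standard(marks: Sequence[int]) -> str:
    """Conservative evaluation label from a 3-reader panel.

    Majority positive -> "positive"; unanimous negative -> "negative"; a lone
    positive -> "excluded" (too ambiguous for a reference standard).
    """
    marks_arr = np.asarray(marks, dtype=int)
    if marks_arr.shape != (3,) or not np.isin(marks_arr, (0, 1)).all():
        raise ValueError("reference_standard expects exactly 3 binary marks")
    pos = int(marks_arr.sum())
    if pos >= 2:
        return "positive"
    if pos == 0:
        return "negative"
    return "excluded"


def fuse_panel(panel: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """EM-fuse every label of a panel into soft targets plus reference status.

    Returns one row per (image, label) with the Naive Bayes posterior (the
    training target) and the conservative reference status (for evaluation
    splits only).
    """
    rows = []
    for label in labels:
        res = em_estimate(panel, label)
        marks, image_ids, _ = panel_matrix(panel, label)
        for i, img in enumerate(image_ids):
            status = (reference_standard(marks[i]) if marks.shape[1] == 3
                      else ("positive" if marks[i].mean() > 0.5 else "negative"))
            rows.append({
                "image_id": img,
                "label": label,
                "posterior": float(res.posteriors.iloc[i]),
                "reference_status": status,
            })
    return pd.DataFrame(rows)
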