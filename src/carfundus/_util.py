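"""Shared numerics: safe sigmoid/logit with explicit clipping policy."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("carfundus")

#: probabilities are clamped into [CLIP, 1-CLIP] before taking logits so that
#: downstream exponentials stay finite; clamping events are logged.
CLIP = 1e-12


def sigmoid(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def logit(p, clip: bool = True):
    """Inverse sigmoid log(p/(1-p)); clamps into (0,1) open interval first."""
    p = np.asarray(p, dtype=float)
    if clip:
        clipped = np.clip(p, CLIP, 1.0 - CLIP)
        if np.any(clipped != p):
            logger.warning("probabilities clamped to [%g, 1-%g] before logit", CLIP, CLIP)
        p = clipped
    else:
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p) - np.log1p(-p)
    if out.ndim == 0:
        return float(out)
    return out


def as_vector(x, name: str = "vector") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr
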