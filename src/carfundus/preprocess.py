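"""Image preprocessing: crop the black background, pad to square, resize.

Fundus photographs sit on a black field; rows and columns whose maximum
intensity stays below a threshold are border, not content.  The crop keeps
the content's bounding box, symmetric zero-padding restores a square frame
(centering the content), and the result is resized to the target edge.
Idempotent on already-processed images.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

#: default black-background threshold on a [0, 1] intensity scale
BLACK_THRESHOLD = 10.0 / 255.0


def preprocess_image(
    image: np.ndarray,
    target_size: int = 64,
    black_threshold: float = BLACK_THRESHOLD,
) -> np.ndarray:
    """Crop black borders, pad to square, and resize to target_size.

    ``image`` is (H, W, 3) float in [0, 1] or uint8; returns float in [0, 1].
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {arr.shape}")

    intensity = arr.max(axis=2)
    keep_rows = np.flatnonzero(intensity.max(axis=1) > black_threshold)
    keep_cols = np.flatnonzero(intensity.max(axis=0) > black_threshold)
    if keep_rows.size == 0 or keep_cols.size == 0:
        raise ValueError("image is entirely black below the background threshold")
    cropped = arr[keep_rows[0]:keep_rows[-1] + 1, keep_cols[0]:keep_cols[-1] + 1]

    h, w, _ = cropped.shape
    side = max(h, w)
    padded = np.zeros((side, side, 3))
    top = (side - h) // 2
    left = (side - w) // 2
    padded[top:top + h, left:left + w] = cropped

    if side == target_size:
        return padded
    img = Image.fromarray((padded * 255.0).round().astype(np.uint8))
    img = img.resize((target_size, target_size), Image.BILINEAR)
    return np.asarray(img, dtype=float) / 255.0
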