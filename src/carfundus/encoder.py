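"""Lightweight convolutional feature extractor with per-finding branches.

A shared stack of convolution stages feeds one branch per finding, mirroring
the shared-encoder / per-task-branch layout used for multi-finding image
classification.  Filters are fixed at construction (seeded): each stage keeps
an identity passthrough for the first ``min(C_in, C_out)`` channels and fills
the rest with random Gaussian filters, so low-level intensity structure
survives to the pooled features while extra channels mix texture.  Only the
linear heads downstream are trained.

Stage = 3x3 "same" convolution -> ReLU -> 2x2 average pooling.
"""

from __future__ import annotations

import numpy as np

from .heads import EncoderSpec, LatentFeatures


def _filter_bank(rng: np.random.Generator, c_in: int, c_out: int) -> np.ndarray:
    w = rng.normal(0.0, 1.0 / np.sqrt(9 * c_in), size=(c_out, c_in, 3, 3))
    # identity passthrough on the leading channels: delta kernel at the center
    for i in range(min(c_in, c_out)):
        w[i] = 0.0
        w[i, i, 1, 1] = 1.0
    return w


def _conv3x3_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x: (n, C_in, H, W), w: (C_out, C_in, 3, 3) -> (n, C_out, H, W)."""
    n, c_in, h, wd = x.shape
    pad = np.zeros((n, c_in, h + 2, wd + 2), dtype=x.dtype)
    pad[:, :, 1:-1, 1:-1] = x
    out = np.zeros((n, w.shape[0], h, wd), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            shifted = pad[:, :, i:i + h, j:j + wd]
            out += np.einsum("nchw,oc->nohw", shifted, w[:, :, i, j], optimize=True)
    return out


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h - h % 2, w - w % 2
    x = x[:, :, :h2, :w2]
    return x.reshape(n, c, h2 // 2, 2, w2 // 2, 2).mean(axis=(3, 5))


class TinyEncoder:
    """Fixed-filter CNN producing per-finding feature maps g_f(x).

    Parameters
    ----------
    spec:
        Shape contract (input size, shared/branch depth, channel count C).
    n_findings:
        Number of per-finding branches F.
    seed:
        Seeds the filter banks; the encoder is a pure function of
        (spec, n_findings, seed).
    """

    def __init__(self, spec: EncoderSpec, n_findings: int, seed: int = 0) -> None:
        if n_findings < 1:
            raise ValueError("need at least one finding branch")
        self.spec = spec
        self.n_findings = int(n_findings)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c = spec.channels
        self.shared_banks = []
        c_in = 3
        for _ in range(spec.shared_depth):
            self.shared_banks.append(_filter_bank(rng, c_in, c))
            c_in = c
        self.branch_banks = [
            [_filter_bank(rng, c, c) for _ in range(spec.branch_depth)]
            for _ in range(n_findings)
        ]

    def _check(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:  # single image H x W x 3
            images = images[None]
        if images.ndim != 4:
            raise ValueError("images must be (n, H, W, 3) or (H, W, 3)")
        if images.shape[-1] == 3:
            images = np.moveaxis(images, -1, 1)
        elif images.shape[1] != 3:
            raise ValueError("expected 3 color channels")
        return images

    def forward(self, images: np.ndarray, batch: int = 128) -> list[list[np.ndarray]]:
        """Return per-image latent maps: list over images of [F maps (C,H',W')]."""
        images = self._check(images)
        outs: list[list[np.ndarray]] = []
        for start in range(0, images.shape[0], batch):
            x = images[start:start + batch]
            for bank in self.shared_banks:
                x = _avgpool2(np.maximum(_conv3x3_same(x, bank), 0.0))
            branch_maps = []
            for f in range(self.n_findings):
                xb = x
                for bank in self.branch_banks[f]:
                    xb = _avgpool2(np.maximum(_conv3x3_same(xb, bank), 0.0))
                branch_maps.append(xb)
            for i in range(x.shape[0]):
                outs.append([branch_maps[f][i] for f in range(self.n_findings)])
        return outs

    def latent(self, image: np.ndarray) -> LatentFeatures:
        """Feature maps and pooled vectors for a single image."""
        maps = self.forward(image[None] if image.ndim == 3 else image)[0]
        return LatentFeatures(per_finding_maps=maps)

    def pooled(self, images: np.ndarray, batch: int = 128) -> np.ndarray:
        """Pooled features for a batch: array (n, F, C)."""
        images = self._check(images)
        n = images.shape[0]
        out = np.empty((n, self.n_findings, self.spec.channels))
        for start in range(0, n, batch):
            x = images[start:start + batch]
            for bank in self.shared_banks:
                x = _avgpool2(np.maximum(_conv3x3_same(x, bank), 0.0))
            for f in range(self.n_findings):
                xb = x
                for bank in self.branch_banks[f]:
                    xb = _avgpool2(np.maximum(_conv3x3_same(xb, bank), 0.0))
                out[start:start + x.shape[0], f, :] = xb.mean(axis=(2, 3))
        return out
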