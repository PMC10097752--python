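"""Synthetic fixtures with known ground truth: toy fundus-like images carrying
per-finding lesion blobs, latent-feature cohorts from a logistic
finding -> disease generative link, and multi-reader annotation panels drawn
from known reader profiles.

All generators are pure functions of (spec, seed): the same spec reproduces
bit-identical output.  The defaults describe a small but fully exercised
study: 64x64 images, three findings with distinct blob signatures, two
diseases with logistic coefficients of magnitude 3 (plus zero and negative
couplings so sign recovery is non-trivial), three readers with sensitivities
(0.9, 0.8, 0.7) and specificities (0.95, 0.9, 0.85), and Gaussian feature
noise 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import sigmoid
from .heads import ModelBundle
from .car import car_matrix


@dataclass
class FindingSpec:
    """One finding's prevalence and its visual blob signature."""

    name: str
    prevalence: float
    blob_count: int = 5
    blob_radius: float = 3.0
    intensity: float = 0.5
    channel: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence of {self.name!r} must be inside (0, 1)")
        if self.blob_count < 1 or self.blob_radius <= 0:
            raise ValueError("blob count and radius must be positive")


@dataclass
class DiseaseSpec:
    """Logistic link from finding presences to one disease."""

    name: str
    coeffs: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.intercept = float(self.intercept)


@dataclass
class GeneratorSpec:
    """Full study description for the synthetic cohort."""

    n_images: int = 2000
    findings: list[FindingSpec] = field(default_factory=lambda: [
        FindingSpec("hemorrhage", 0.35, blob_count=6, blob_radius=3.0,
                    intensity=0.55, channel=0),
        FindingSpec("hard_exudate", 0.30, blob_count=4, blob_radius=2.5,
                    intensity=0.6, channel=1),
        FindingSpec("drusen", 0.25, blob_count=8, blob_radius=2.0,
                    intensity=0.5, channel=2),
    ])
    diseases: list[DiseaseSpec] = field(default_factory=lambda: [
        DiseaseSpec("retinopathy", np.array([3.0, 3.0, 0.0]), -2.0),
        DiseaseSpec("maculopathy", np.array([0.0, -3.0, 3.0]), -1.0),
    ])
    reader_sens: tuple[float, ...] = (0.9, 0.8, 0.7)
    reader_spec: tuple[float, ...] = (0.95, 0.9, 0.85)
    image_size: int = 64
    feature_dim: int = 8
    feature_scale: float = 3.0
    noise: float = 0.3
    pixel_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for d in self.diseases:
            if d.coeffs.shape != (len(self.findings),):
                raise ValueError(f"disease {d.name!r} needs one coefficient per finding")
        for p in (*self.reader_sens, *self.reader_spec):
            if not (0.0 < p < 1.0):
                raise ValueError("reader profiles must lie inside (0, 1)")
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64")

    @property
    def finding_names(self) -> list[str]:
        return [f.name for f in self.findings]

    @property
    def disease_names(self) -> list[str]:
        return [d.name for d in self.diseases]


@dataclass
class Cohort:
    """Latent-feature cohort with ground truth."""

    features: np.ndarray        # (n, F, C)
    finding_truth: np.ndarray   # (n, F) binary
    disease_truth: np.ndarray   # (n, D) binary
    directions: np.ndarray      # (F, C) unit directions u_f
    spec: GeneratorSpec


def _draw_diseases(presence: np.ndarray, spec: GeneratorSpec,
                   rng: np.random.Generator) -> np.ndarray:
    n = presence.shape[0]
    out = np.empty((n, len(spec.diseases)), dtype=int)
    for d, ds in enumerate(spec.diseases):
        p = sigmoid(presence @ ds.coeffs + ds.intercept)
        out[:, d] = rng.random(n) < p
    return out


def simulate_cohort(spec: GeneratorSpec) -> Cohort:
    """Draw pooled features directly from the generative model.

    Finding presence ~ Bernoulli(pi_f); the pooled feature for finding f is
    presence * mu * u_f plus isotropic Gaussian noise, with u_f a fixed unit
    direction per finding; disease truth ~ Bernoulli(sigma(beta . presence +
    beta_0)).
    """
    rng = np.random.default_rng(spec.seed)
    F, C, n = len(spec.findings), spec.feature_dim, spec.n_images
    directions = rng.normal(size=(F, C))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    presence = np.empty((n, F), dtype=int)
    for f, fs in enumerate(spec.findings):
        presence[:, f] = rng.random(n) < fs.prevalence
    features = spec.noise * rng.normal(size=(n, F, C))
    features += presence[:, :, None] * spec.feature_scale * directions[None, :, :]
    diseases = _draw_diseases(presence, spec, rng)
    return Cohort(features, presence, diseases, directions, spec)


@dataclass
class ImageSet:
    """Rendered toy images with ground truth."""

    images: np.ndarray          # (n, H, W, 3) float in [0, 1]
    finding_truth: np.ndarray   # (n, F)
    disease_truth: np.ndarray   # (n, D)
    spec: GeneratorSpec

    def truth_frame(self) -> pd.DataFrame:
        data = {"image_id": [f"img{i:05d}" for i in range(self.images.shape[0])]}
        for f, name in enumerate(self.spec.finding_names):
            data[name] = self.finding_truth[:, f]
        for d, name in enumerate(self.spec.disease_names):
            data[name] = self.disease_truth[:, d]
        return pd.DataFrame(data)


def _disc_mask(size: int) -> tuple[np.ndarray, float, float]:
    yy, xx = np.mgrid[0:size, 0:size]
    center = (size - 1) / 2.0
    radius = size * 0.44
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= radius ** 2
    return mask, center, radius


def render_toy_images(spec: GeneratorSpec) -> ImageSet:
    """Render fundus-like discs; each present finding adds its blob signature.

    The disc sits on a black background in warm base tones; a finding adds
    ``blob_count`` Gaussian-profile blobs of its intensity to its color
    channel at seeded positions inside the disc.  Absent findings leave the
    image identical to the lesion-free base for that seed.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    mask, center, radius = _disc_mask(size)
    for fs in spec.findings:
        if fs.blob_radius >= radius:
            raise ValueError(f"blob radius {fs.blob_radius} of {fs.name!r} exceeds "
                             f"the disc radius {radius:.1f}")
    F, n = len(spec.findings), spec.n_images
    presence = np.empty((n, F), dtype=int)
    for f, fs in enumerate(spec.findings):
        presence[:, f] = rng.random(n) < fs.prevalence
    diseases = _draw_diseases(presence, spec, rng)

    base_color = np.array([0.55, 0.35, 0.15])
    yy, xx = np.mgrid[0:size, 0:size]
    images = np.zeros((n, size, size, 3))
    for i in range(n):
        img = np.zeros((size, size, 3))
        img[mask] = base_color
        img += spec.pixel_noise * rng.normal(size=img.shape)
        for f, fs in enumerate(spec.findings):
            # fixed-length consumption of the random stream per finding keeps
            # the lesion-free base pixel-identical across presence patterns
            angles = rng.uniform(0, 2 * np.pi, fs.blob_count)
            radii = (radius - fs.blob_radius - 1) * np.sqrt(rng.random(fs.blob_count))
            if not presence[i, f]:
                continue
            cy = center + radii * np.sin(angles)
            cx = center + radii * np.cos(angles)
            for b in range(fs.blob_count):
                bump = np.exp(-(((yy - cy[b]) ** 2 + (xx - cx[b]) ** 2)
                                / (2.0 * (fs.blob_radius / 1.5) ** 2)))
                img[:, :, fs.channel] += fs.intensity * bump
        img *= mask[:, :, None]
        images[i] = np.clip(img, 0.0, 1.0)
    return ImageSet(images, presence, diseases, spec)


def save_images_png(imageset: ImageSet, out_dir) -> list[str]:
    """Write each image as an 8-bit PNG; returns the file names."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(imageset.images.shape[0]):
        arr = (imageset.images[i] * 255.0).round().astype(np.uint8)
        name = f"img{i:05d}.png"
        Image.fromarray(arr).save(out / name)
        names.append(name)
    return names


def simulate_reader_panel(
    truths: pd.DataFrame,
    labels: Sequence[str],
    sens: Sequence[float],
    spec: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a reader panel: independent marks given truth per reader profile.

    ``truths`` has an ``image_id`` column plus one binary column per label.
    Reader a marks a truly-positive image with probability sens[a] and a
    truly-negative one with probability 1 - spec[a].
    """
    sens = np.asarray(sens, dtype=float)
    spec_arr = np.asarray(spec, dtype=float)
    if np.any((sens <= 0) | (sens >= 1)) or np.any((spec_arr <= 0) | (spec_arr >= 1)):
        raise ValueError("reader profiles must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(truths)
    rows = []
    for a in range(sens.size):
        block = {"image_id": truths["image_id"].to_numpy(),
                 "reader_id": np.repeat(f"reader{a}", n)}
        for label in labels:
            y = truths[label].to_numpy(dtype=int)
            p = np.where(y == 1, sens[a], 1.0 - spec_arr[a])
            block[label] = (rng.random(n) < p).astype(int)
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)


def ground_truth_car_agreement(
    spec: GeneratorSpec,
    model: ModelBundle,
    eps: float = 0.005,
    floor: float = 1.0,
) -> dict:
    """Compare the trained model's CAR sign pattern to the generator's beta signs.

    Over finding-disease pairs whose |beta| is at least ``floor``, reports the
    fraction where sign(log CAR) matches sign(beta), plus the raw grids.
    """
    cm = car_matrix(model, eps)
    log_car = cm.log_values()
    beta = np.stack([d.coeffs for d in spec.diseases], axis=1)  # (F, D)
    strong = np.abs(beta) >= floor
    if not strong.any():
        raise ValueError(f"no generator pairs with |beta| >= {floor}")
    agree = np.sign(log_car[strong]) == np.sign(beta[strong])
    return {
        "agreement": float(np.mean(agree)),
        "n_pairs": int(strong.sum()),
        "log_car": log_car,
        "beta": beta,
        "strong_mask": strong,
    }
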