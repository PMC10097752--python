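"""Per-image explanation reports: disease probabilities, the strongest
findings by instance-dependent CAR, optional interactive overrides, and
attribution overlays, with enough provenance (model hash, epsilon, seed) to
reproduce the output bit-for-bit."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .car import DISPLAY_THRESHOLD, attribution_map, explain_instance, interactive_adjust
from .heads import LatentFeatures, ModelBundle
from .serialize import model_hash


def build_report(
    latents: LatentFeatures,
    model: ModelBundle,
    eps: float,
    image_id: str = "image",
    overrides: Mapping[str, float] | None = None,
    threshold: float = DISPLAY_THRESHOLD,
    k: int = 3,
    seed: int | None = None,
) -> dict:
    """Assemble the explanation report for one image as a JSON-ready dict."""
    result = explain_instance(latents.pooled, model, eps=eps, threshold=threshold, k=k)
    report = {
        "image_id": image_id,
        "provenance": {
            "model_hash": model_hash(model),
            "epsilon": eps,
            "threshold": threshold,
            "seed": seed,
            "package_version": __version__,
        },
        "finding_scores": result["finding_scores"],
        "disease_scores": result["disease_scores"],
        "top_findings": {
            d: [{"finding": f, "icar": v} for f, v in pairs]
            for d, pairs in result["top_findings"].items()
        },
        "icar": {
            f: dict(zip(model.disease_names, result["icar"][i].tolist()))
            for i, f in enumerate(model.finding_names)
        },
    }
    if overrides:
        adjusted = interactive_adjust(latents.pooled, model, overrides)
        report["overrides"] = {
            "requested": {k_: float(v) for k_, v in overrides.items()},
            "original_disease_scores": result["disease_scores"],
            "adjusted_disease_scores": dict(zip(model.disease_names, adjusted.tolist())),
        }
    return report


def write_report(report: dict, path) -> None:
    """Serialize a report deterministically (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def attribution_overlay_png(
    image: np.ndarray,
    latents: LatentFeatures,
    model: ModelBundle,
    finding: str,
    disease: str,
    path,
) -> None:
    """Save the image with its attribution map blended on top.

    For rendering only, the map is normalized to [-1, 1] by its maximum
    absolute value; positive attribution is tinted red, negative blue.  Raw
    attribution values live in the JSON report / CSV exports, not the PNG.
    """
    from PIL import Image

    f = model.finding_index(finding)
    d = model.disease_names.index(disease)
    amap = attribution_map(latents.per_finding_maps[f], model.findings[f],
                           model.diseases[d], f)
    arr = np.asarray(image, dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    size = arr.shape[0]
    up = amap.upsample(size)
    peak = float(np.abs(up).max())
    norm = up / peak if peak > 0 else up
    overlay = arr.copy()
    overlay[:, :, 0] = np.clip(overlay[:, :, 0] + 0.6 * np.maximum(norm, 0.0), 0, 1)
    overlay[:, :, 2] = np.clip(overlay[:, :, 2] + 0.6 * np.maximum(-norm, 0.0), 0, 1)
    Image.fromarray((overlay * 255.0).round().astype(np.uint8)).save(path)


def export_car_csv(car_frame, path) -> None:
    """CAR matrix as CSV: finding rows, disease columns."""
    car_frame.to_csv(path, float_format="%.10g")


def write_manifest(path, config_echo: Mapping, seed: int) -> None:
    """Run manifest: config echo + seed + version, enough to reproduce outputs."""
    manifest = {
        "config": dict(config_echo),
        "seed": seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
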