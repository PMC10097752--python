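"""Model bundle serialization: a JSON header (names, F, D, C) plus one CSV
matrix per head family.  Round trips are bit-exact for the header and exact
to float64 for the matrices (values written with 17 significant digits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .heads import DiseaseHead, FindingHead, ModelBundle

_HEADER = "model.json"
_FINDINGS = "finding_heads.csv"
_DISEASES = "disease_heads.csv"


def save_model(bundle: ModelBundle, path) -> None:
    """Write a bundle to a directory: header JSON + two CSV weight tables."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    C = bundle.channels
    header = {
        "format": "carfundus-model",
        "version": 1,
        "findings": bundle.finding_names,
        "diseases": bundle.disease_names,
        "n_findings": len(bundle.findings),
        "n_diseases": len(bundle.diseases),
        "channels": C,
    }
    (out / _HEADER).write_text(json.dumps(header, indent=2))

    frows = {"name": bundle.finding_names}
    for c in range(C):
        frows[f"w{c}"] = [h.weight[c] for h in bundle.findings]
    frows["bias"] = [h.bias for h in bundle.findings]
    pd.DataFrame(frows).to_csv(out / _FINDINGS, index=False, float_format="%.17g")

    drows = {"name": bundle.disease_names}
    for f, fname in enumerate(bundle.finding_names):
        for c in range(C):
            drows[f"v_{fname}_{c}"] = [h.blocks[f][c] for h in bundle.diseases]
    drows["intercept"] = [h.intercept for h in bundle.diseases]
    pd.DataFrame(drows).to_csv(out / _DISEASES, index=False, float_format="%.17g")


def load_model(path) -> ModelBundle:
    """Read a bundle back; raises a clear format error on malformed input."""
    root = Path(path)
    header_path = root / _HEADER
    if not header_path.exists():
        raise FileNotFoundError(f"no model header at {header_path}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model header {header_path}: {exc}") from exc
    if header.get("format") != "carfundus-model":
        raise ValueError(f"{header_path} is not a model header (format field missing)")
    findings = header["findings"]
    diseases = header["diseases"]
    C = int(header["channels"])

    ftab = pd.read_csv(root / _FINDINGS, float_precision="round_trip")
    finding_heads = []
    for name in findings:
        row = ftab[ftab["name"] == name]
        if row.empty:
            raise ValueError(f"finding head {name!r} missing from {_FINDINGS}")
        w = row[[f"w{c}" for c in range(C)]].to_numpy(dtype=float)[0]
        finding_heads.append(FindingHead(name, w, float(row["bias"].iloc[0])))

    dtab = pd.read_csv(root / _DISEASES, float_precision="round_trip")
    disease_heads = []
    for name in diseases:
        row = dtab[dtab["name"] == name]
        if row.empty:
            raise ValueError(f"disease head {name!r} missing from {_DISEASES}")
        blocks = []
        for fname in findings:
            cols = [f"v_{fname}_{c}" for c in range(C)]
            missing = [c for c in cols if c not in dtab.columns]
            if missing:
                raise ValueError(
                    f"disease head {name!r} is missing the block for finding "
                    f"{fname!r} (columns {missing[:1]}...)"
                )
            blocks.append(row[cols].to_numpy(dtype=float)[0])
        disease_heads.append(DiseaseHead(name, blocks, float(row["intercept"].iloc[0])))
    return ModelBundle(finding_heads, disease_heads)


def model_hash(bundle: ModelBundle) -> str:
    """Stable content hash of all parameters (for report provenance)."""
    h = hashlib.sha256()
    for head in bundle.findings:
        h.update(head.name.encode())
        h.update(np.ascontiguousarray(head.weight, dtype=np.float64).tobytes())
        h.update(np.float64(head.bias).tobytes())
    for head in bundle.diseases:
        h.update(head.name.encode())
        for b in head.blocks:
            h.update(np.ascontiguousarray(b, dtype=np.float64).tobytes())
        h.update(np.float64(head.intercept).tobytes())
    return h.hexdigest()[:16]
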