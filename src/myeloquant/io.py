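"""Image and table I/O: multi-channel TIFF with a JSON sidecar, manifest CSVs.

A multiplex image is stored as a (C, H, W) TIFF stack plus a sidecar JSON
(``<image>.json``) recording marker names in channel order, the pixel size
in µm and the case metadata.  Alternatively a manifest CSV (columns:
marker, path) points at single-channel TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .segmentation import MultiplexImage


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(str(tiff_path) + ".json")


def write_multiplex(image: MultiplexImage, path: str | Path) -> Path:
    """Write channels as a (C, H, W) TIFF and metadata as sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([image.channels[m] for m in image.markers]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "markers": list(image.markers),
        "pixel_size_um": image.pixel_size_um,
        "case_id": image.case_id,
        "tissue_type": image.tissue_type,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_multiplex(path: str | Path, sidecar: str | Path | None = None) -> MultiplexImage:
    """Read a multi-channel TIFF + sidecar JSON back into a MultiplexImage."""
    path = Path(path)
    side = Path(sidecar) if sidecar else sidecar_path(path)
    if not side.exists():
        raise ValidationError(f"sidecar JSON not found: {side}")
    meta = json.loads(side.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(meta["markers"]):
        raise ValidationError(
            f"TIFF has {stack.shape[0]} channels but sidecar lists {len(meta['markers'])} markers"
        )
    channels = {m: stack[i].astype(np.float64) for i, m in enumerate(meta["markers"])}
    return MultiplexImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        case_id=meta.get("case_id", path.stem),
        tissue_type=meta.get("tissue_type", "grade_iv"),
    )


def read_manifest(manifest_csv: str | Path) -> MultiplexImage:
    """Assemble an image from a manifest CSV of single-channel TIFFs.

    Required columns: marker, path.  Optional: pixel_size_um, case_id,
    tissue_type (constant per manifest).
    """
    man = pd.read_csv(manifest_csv)
    for c in ("marker", "path"):
        if c not in man.columns:
            raise ValidationError(f"manifest missing column {c!r}")
    base = Path(manifest_csv).parent
    channels = {}
    for _, row in man.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        channels[str(row["marker"])] = tifffile.imread(p).astype(np.float64)
    return MultiplexImage(
        channels=channels,
        pixel_size_um=float(man["pixel_size_um"].iloc[0]) if "pixel_size_um" in man else 0.5,
        case_id=str(man["case_id"].iloc[0]) if "case_id" in man else Path(manifest_csv).stem,
        tissue_type=str(man["tissue_type"].iloc[0]) if "tissue_type" in man else "grade_iv",
    )
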