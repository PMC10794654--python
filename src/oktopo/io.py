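"""Disk formats: PNG images/masks, JSONL dataset manifests.

Masks are stored as single-channel PNGs with values 0/255 and binarised on
read at >127.  A dataset manifest is JSON lines, one record per case:
``{image_path, pupil_mask_path, tz_mask_path, px_per_mm,
true_decentration_mm, true_edcr, true_class, params}`` with paths relative
to the manifest's directory.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .types import PUPIL, TREATMENT_ZONE, RegionMask, TopographyImage

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "save_dataset",
    "load_manifest",
    "load_case_arrays",
]


def write_image(path, image) -> None:
    px = image.pixels if isinstance(image, TopographyImage) else np.asarray(image)
    Image.fromarray(px.astype(np.uint8), mode="RGB").save(path)


def read_image(path, px_per_mm: float = 50.0) -> TopographyImage:
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return TopographyImage(px, px_per_mm=px_per_mm)


def write_mask(path, mask) -> None:
    m = mask.pixels if isinstance(mask, RegionMask) else np.asarray(mask)
    Image.fromarray(((m > 0) * 255).astype(np.uint8), mode="L").save(path)


def read_mask(path, role: str = PUPIL) -> RegionMask:
    with Image.open(path) as im:
        m = np.asarray(im.convert("L"))
    return RegionMask((m > 127).astype(np.uint8), role=role)


def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    for key in ("image_size_px", "pupil_center_px", "tz_center_px"):
        d[key] = list(d[key])
    return d


def save_dataset(cases, out_dir) -> Path:
    """Write images, masks and the JSONL manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for i, case in enumerate(cases):
            stem = f"case_{i:04d}"
            image_path = f"images/{stem}.png"
            pupil_path = f"masks/{stem}_pupil.png"
            tz_path = f"masks/{stem}_tz.png"
            write_image(out / image_path, case.image)
            write_mask(out / pupil_path, case.pupil_mask)
            write_mask(out / tz_path, case.tz_mask)
            record = {
                "image_path": image_path,
                "pupil_mask_path": pupil_path,
                "tz_mask_path": tz_path,
                "px_per_mm": case.image.px_per_mm,
                "true_decentration_mm": case.true_indicators.decentration_mm,
                "true_edcr": case.true_indicators.edcr,
                "true_class": case.true_class.value,
                "params": _params_dict(case.params),
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    return manifest


def load_manifest(manifest_path) -> list[dict]:
    path = Path(manifest_path)
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def load_case_arrays(record: dict, root) -> tuple[TopographyImage, RegionMask, RegionMask]:
    """Materialise (image, pupil mask, tz mask) for one manifest record."""
    root = Path(root)
    ppm = float(record.get("px_per_mm", 50.0))
    image = read_image(root / record["image_path"], px_per_mm=ppm)
    pupil = read_mask(root / record["pupil_mask_path"], role=PUPIL)
    tz = read_mask(root / record["tz_mask_path"], role=TREATMENT_ZONE)
    return image, pupil, tz
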