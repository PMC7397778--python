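"""Reading and writing the on-disk formats used by the CLI.

Images are 8-bit RGB PNG; annotations and detections are plain CSV
(``case_id,row,col,label`` and ``case_id,row,col,label,score``); a dataset
manifest JSON lists the image files and their annotation source; output
maps and model checkpoints are ``.npz`` archives, checkpoints with a sidecar
JSON recording the spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import nn
from .regression import Regressor, RegressorSpec
from .translation import GeneratorSpec, ResnetGenerator
from .types import AnnotatedImage, PointAnnotation

ANNOTATION_COLUMNS = ["case_id", "row", "col", "label"]
DETECTION_COLUMNS = ["case_id", "row", "col", "label", "score"]


def write_dataset(images: list[AnnotatedImage], out_dir: str | Path) -> Path:
    """Write PNGs, one pooled annotations CSV and a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    entries = []
    for im in images:
        png = out / f"{im.case_id}.png"
        iio.imwrite(png, (np.clip(im.pixels, 0, 1) * 255).round().astype(np.uint8))
        for a in im.annotations:
            records.append(
                {"case_id": im.case_id, "row": a.row, "col": a.col, "label": a.label}
            )
        entries.append({"case_id": im.case_id, "image": png.name})
    pd.DataFrame(records, columns=ANNOTATION_COLUMNS).to_csv(
        out / "annotations.csv", index=False
    )
    manifest = {"images": entries, "annotations": "annotations.csv"}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_dataset(manifest_path: str | Path) -> list[AnnotatedImage]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    ann = pd.read_csv(root / manifest["annotations"])
    images = []
    for entry in manifest["images"]:
        pixels = iio.imread(root / entry["image"]).astype(np.float32) / 255.0
        rows = ann[ann["case_id"] == entry["case_id"]]
        annotations = [
            PointAnnotation(int(r.row), int(r.col), str(r.label))
            for r in rows.itertuples()
        ]
        images.append(AnnotatedImage(pixels, annotations, entry["case_id"]))
    return images


def write_detections(per_case: dict[str, list], path: str | Path) -> None:
    records = [
        {"case_id": cid, "row": d.row, "col": d.col, "label": d.label, "score": d.score}
        for cid, dets in per_case.items()
        for d in dets
    ]
    pd.DataFrame(records, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def save_maps(maps: dict[str, np.ndarray], path: str | Path) -> None:
    np.savez_compressed(path, **maps)


def load_maps(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def save_checkpoint(model: nn.Module, spec, seed: int, path: str | Path) -> None:
    path = Path(path)
    state = model.state_dict()
    np.savez_compressed(path, **{f"p{i}": arr for i, arr in enumerate(state)})
    sidecar = {
        "spec_type": type(spec).__name__,
        "spec": dataclasses.asdict(spec),
        "seed": seed,
        "n_params": len(state),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path):
    """Rebuild a generator or regressor from an ``.npz`` + sidecar pair."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        state = [data[f"p{i}"] for i in range(sidecar["n_params"])]
    if sidecar["spec_type"] == "GeneratorSpec":
        model = ResnetGenerator(GeneratorSpec(**sidecar["spec"]), sidecar["seed"])
    elif sidecar["spec_type"] == "RegressorSpec":
        model = Regressor(RegressorSpec(**sidecar["spec"]), sidecar["seed"])
    else:
        raise ValueError(f"unknown checkpoint spec type {sidecar['spec_type']!r}")
    model.load_state_dict(state)
    return model
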