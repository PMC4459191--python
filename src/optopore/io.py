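"""File readers/writers binding the pipeline into reproducible runs.

Conventions: grayscale images as single-channel TIFF (12-bit data in the
low bits of uint16) or 8-bit PNG; target lists as CSV/JSON; ground truth
as JSON (cells) plus a TIFF label image; parameters and thresholds as
YAML; run logs as JSON-lines plus a summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from imageio.v3 import imread as _png_imread, imwrite as _png_imwrite

from .classify import ThresholdSet
from .detect import DetectionParams, TargetPosition
from .scan import RunLog
from .scene import GroundTruth, SceneSpec

TARGET_COLUMNS = ["id", "row_px", "col_px", "x_um", "y_um", "rake_line_index", "status"]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(_png_imread(path))


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        _png_imwrite(path, image)


def targets_to_frame(positions: list[TargetPosition]) -> pd.DataFrame:
    rows = [
        {
            "id": i,
            "row_px": p.row_px,
            "col_px": p.col_px,
            "x_um": p.x_um,
            "y_um": p.y_um,
            "rake_line_index": p.rake_line_index,
            "status": p.status,
        }
        for i, p in enumerate(positions)
    ]
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def write_targets_csv(path, positions: list[TargetPosition]) -> None:
    targets_to_frame(positions).to_csv(path, index=False)


def read_targets_csv(path) -> list[TargetPosition]:
    df = pd.read_csv(path)
    return [
        TargetPosition(
            row_px=int(r.row_px),
            col_px=int(r.col_px),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            rake_line_index=int(r.rake_line_index),
            status=str(r.status),
        )
        for r in df.itertuples()
    ]


def write_targets_json(path, positions: list[TargetPosition]) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(p) for p in positions], indent=1)
    )


def write_truth(dirpath, truth: GroundTruth, stem: str = "truth") -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    (dirpath / f"{stem}_cells.json").write_text(truth.cells_to_json())
    tifffile.imwrite(dirpath / f"{stem}_labels.tif", truth.label_image.astype(np.int32))


def read_truth(dirpath, stem: str = "truth") -> GroundTruth:
    dirpath = Path(dirpath)
    labels = tifffile.imread(dirpath / f"{stem}_labels.tif")
    return GroundTruth.cells_from_json((dirpath / f"{stem}_cells.json").read_text(), labels)


def scene_spec_to_yaml(spec: SceneSpec) -> str:
    return yaml.safe_dump(spec.to_dict(), sort_keys=False)


def scene_spec_from_yaml(text: str) -> SceneSpec:
    return SceneSpec.from_dict(yaml.safe_load(text))


def detection_params_from_dict(d: dict) -> DetectionParams:
    return DetectionParams(**d)


def thresholds_to_yaml(path, thresholds: ThresholdSet) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(thresholds), sort_keys=False))


def thresholds_from_yaml(path) -> ThresholdSet:
    return ThresholdSet(**yaml.safe_load(Path(path).read_text()))


def write_runlog(dirpath, log: RunLog, stem: str = "run") -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    (dirpath / f"{stem}_events.jsonl").write_text(log.to_jsonl() + "\n")
    (dirpath / f"{stem}_summary.json").write_text(json.dumps(log.summary(), indent=1))


def read_calibration_csv(path) -> np.ndarray:
    """Focus calibration points as an (n, 3) array from x_um,y_um,z_um columns."""
    df = pd.read_csv(path)
    return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
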