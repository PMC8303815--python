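"""File formats, configuration and manifests.

Conventions: images are grayscale PNG/TIFF (intensities mapped to [0, 1] on
load); masks are single-channel PNG with 0 = background, 255 = lesion;
polygons are CSV vertex lists (``row,col`` per line); layer bands are JSON;
feature tables and reports are CSV/JSON; run configuration is YAML.  Every
file the package writes can be read back by the package.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classify import EvaluationReport, MODES, TASKS
from .errors import ManifestError
from .phantom import ClassAppearance, PhantomSpec
from .segmentation import SkinLayers

LABELS = ("nevus", "BCC", "MM")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters, serializable to/from YAML."""

    segmentation: str = "fa"          # fa | freehand | lar
    lane_width: int = 5
    dermis_depth: int | None = None
    glcm_levels: int = 16
    acm_iterations: int = 200
    acm_smoothing: int = 1
    seed_threshold_k: float = 1.0
    svm_c: float = 1.0
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.segmentation not in ("fa", "freehand", "lar"):
            raise ManifestError(f"unknown segmentation mode {self.segmentation!r}")
        if not (1 <= self.lane_width <= 50 and 2 <= self.glcm_levels <= 256
                and self.acm_iterations >= 0 and self.folds >= 1
                and self.svm_c > 0):
            raise ManifestError("run-config parameter out of range")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class Manifest:
    """Dataset listing: image path, optional mask/polygon paths, label."""

    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)


def load_manifest(path) -> Manifest:
    """Load and validate a CSV manifest.

    Columns: ``image`` (required), ``mask``, ``polygon`` (optional paths,
    relative to the manifest), ``label`` (optional; must be one of
    nevus/BCC/MM when present).  Referenced files must exist.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ManifestError(f"manifest is empty: {path}") from exc
    if df.empty:
        raise ManifestError(f"manifest has no data rows: {path}")
    if "image" not in df.columns:
        raise ManifestError("manifest needs an 'image' column")
    base = path.parent
    rows = []
    for n, rec in df.iterrows():
        row = {"image": base / str(rec["image"])}
        if not row["image"].exists():
            raise ManifestError(f"row {n}: image file missing: {row['image']}")
        for key in ("mask", "polygon"):
            if key in df.columns and pd.notna(rec.get(key)) and str(rec[key]):
                p = base / str(rec[key])
                if not p.exists():
                    raise ManifestError(f"row {n}: {key} file missing: {p}")
                row[key] = p
        label = rec.get("label")
        if pd.notna(label) and str(label):
            if str(label) not in LABELS:
                raise ManifestError(
                    f"row {n}: label {label!r} is not one of {LABELS}")
            row["label"] = str(label)
        rows.append(row)
    return Manifest(rows=rows)


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float in [0, 1]."""
    img = np.asarray(Image.open(path).convert("F"), dtype=float)
    peak = img.max()
    return img / peak if peak > 1.0 else img


def write_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] image as 8-bit grayscale (quantized only on export)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


def write_mask(mask: np.ndarray, path) -> None:
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_polygon(path) -> np.ndarray:
    verts = np.loadtxt(path, delimiter=",", ndmin=2)
    if verts.shape[1] != 2:
        raise ManifestError("polygon CSV must have two columns (row,col)")
    return verts


def write_polygon(vertices: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(vertices, dtype=float), delimiter=",", fmt="%.3f")


def write_layers(layers: SkinLayers, path) -> None:
    Path(path).write_text(json.dumps({
        "epidermis_top": layers.epidermis_top.tolist(),
        "dermis_top": layers.dermis_top.tolist(),
        "dermis_bottom": layers.dermis_bottom.tolist(),
    }))


def read_layers(path) -> SkinLayers:
    d = json.loads(Path(path).read_text())
    return SkinLayers(epidermis_top=np.asarray(d["epidermis_top"], dtype=int),
                      dermis_top=np.asarray(d["dermis_top"], dtype=int),
                      dermis_bottom=np.asarray(d["dermis_bottom"], dtype=int))


def phantom_spec_from_yaml(path) -> PhantomSpec:
    """Build a PhantomSpec from a flat YAML config (missing keys default)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    class_params = cfg.pop("class_params", None)
    spec_kwargs = dict(cfg)
    if class_params is not None:
        spec_kwargs["class_params"] = {
            name: ClassAppearance(**params) for name, params in class_params.items()}
    return PhantomSpec(**spec_kwargs)


def write_reports(reports: list[EvaluationReport], json_path,
                  csv_path=None) -> None:
    """Write evaluation reports as JSON plus a task-grid CSV.

    The CSV mirrors the familiar results layout: one row per task, one
    column per mode x metric.  An empty report list is an error — never an
    empty file.
    """
    reports = list(reports)
    if not reports:
        raise ManifestError("refusing to write an empty report")
    Path(json_path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))
    if csv_path is not None:
        by_key = {(r.task, r.mode): r for r in reports}
        rows = []
        for task in TASKS:
            row = {"task": task}
            for mode in MODES:
                r = by_key.get((task, mode))
                if r is not None:
                    row[f"auc_{mode}"] = r.auc
                    row[f"acc_{mode}"] = r.acc
            if len(row) > 1:
                rows.append(row)
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_reports(json_path) -> list[EvaluationReport]:
    return [EvaluationReport.from_dict(d)
            for d in json.loads(Path(json_path).read_text())]
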