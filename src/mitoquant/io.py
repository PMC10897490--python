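"""Readers, writers and run configuration.

All images travel as TIFF, all tables as UTF-8 CSV with a header row,
and the run configuration as YAML.  Stacks are normalized in memory to
a fixed (t, channel, row, col) axis order so downstream code never
guesses at axis meaning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .contacts import AnnotatedScene
from .morphology import ClassificationParams
from .segmentation import MitoObject, SegmentationParams
from .tethering import TrackingParams

__all__ = [
    "read_stack",
    "write_stack",
    "read_annotation_csv",
    "write_annotation_csv",
    "objects_to_frame",
    "RunConfig",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF as a (t, channel, row, col) array.

    Axis metadata is honoured when present; otherwise a 2D page is a
    single frame/channel, a 3D series is taken as (t, row, col), and a
    4D one as (t, channel, row, col).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
    except (OSError, ValueError, IndexError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc

    if data.ndim == 2:
        return data[None, None]
    if data.ndim == 3:
        if "C" in axes and "T" not in axes:
            return data[None]  # (C, Y, X)
        return data[:, None]  # (T, Y, X)
    if data.ndim == 4:
        if axes.startswith("CT"):
            return np.swapaxes(data, 0, 1)
        return data  # assume (T, C, Y, X)
    raise OSError(f"unsupported TIFF dimensionality {data.shape} in {path}")


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (t, channel, row, col) stack with axis metadata."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None, None]
    if stack.ndim != 4:
        raise ValueError(f"expected (T, C, H, W), got shape {stack.shape}")
    tifffile.imwrite(path, stack.astype(np.float32), metadata={"axes": "TCYX"})


ANNOTATION_COLUMNS = ["cell_id", "object_type", "object_id", "vertex_index", "x_nm", "y_nm"]


def write_annotation_csv(scenes: list[AnnotatedScene], path: str | Path) -> None:
    """Write traced scenes as one vertex per row."""
    rows = []
    for scene in scenes:
        for kind, objects in (("mito", scene.mito_polygons), ("er", scene.er_polylines)):
            for oid, coords in enumerate(objects):
                for vi, (x, y) in enumerate(np.asarray(coords, dtype=float)):
                    rows.append((scene.cell_id, kind, oid, vi, x, y))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotation_csv(path: str | Path) -> list[AnnotatedScene]:
    """Read traced scenes; one :class:`AnnotatedScene` per cell_id."""
    df = pd.read_csv(path)
    if missing := set(ANNOTATION_COLUMNS) - set(df.columns):
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    scenes = []
    for cell_id, cell in df.groupby("cell_id", sort=False):
        polys, lines = [], []
        for (kind, oid), obj in cell.sort_values("vertex_index").groupby(
            ["object_type", "object_id"], sort=False
        ):
            coords = obj[["x_nm", "y_nm"]].to_numpy(dtype=float)
            (polys if kind == "mito" else lines).append(coords)
        scenes.append(AnnotatedScene(mito_polygons=polys, er_polylines=lines, cell_id=str(cell_id)))
    return scenes


def objects_to_frame(objects: list[MitoObject], cell_id: str = "") -> pd.DataFrame:
    """Per-object table with the standard column layout."""
    return pd.DataFrame(
        [
            {
                "cell_id": cell_id,
                "label": o.label,
                "area_px": o.area_px,
                "perimeter_px": o.perimeter_px,
                "aspect_ratio": o.aspect_ratio,
                "centroid_row": o.centroid[0],
                "centroid_col": o.centroid[1],
            }
            for o in objects
        ]
    )


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable configuration of one pipeline run."""

    um_per_px: float = 0.1
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    contact_step_nm: float = 5.0
    contact_max_gap_nm: float = 60.0
    fusion_threshold_fraction: float = 0.2
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("segmentation", SegmentationParams),
            ("classification", ClassificationParams),
            ("tracking", TrackingParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
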