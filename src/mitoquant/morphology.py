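"""Per-cell mitochondrial morphology: AR statistics and network classification.

A cell's mitochondrial network is summarized by the mean aspect ratio of
its segmented mitochondria and assigned one of five classes:

* ``Elongated`` — more than ``class_fraction`` of objects are tubular
  (AR >= ``tubular_ar_min``).
* ``Fragmented`` — more than ``class_fraction`` of objects are round.
* ``Hyperfused`` — a single highly interconnected component dominates the
  network (largest component holds >= ``hyperfused_component_fraction``
  of total mitochondrial area and is tubular/reticular rather than
  blob-like).
* ``Collapsed`` — the network is clumped: at least
  ``collapsed_area_fraction`` of mitochondrial area lies within
  ``collapsed_radius_fraction`` of the image diagonal from the
  mitochondrial area centroid.
* ``Intermediate`` — none of the above; the four named phenotypes are
  not exhaustive once made rule-explicit.

Rules are evaluated in priority order Collapsed -> Hyperfused ->
Elongated -> Fragmented -> Intermediate, so a clumped or reticular
network is never mis-read through its per-object shape statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segmentation import MitoObject

__all__ = [
    "ClassificationParams",
    "CellMorphology",
    "CLASS_NAMES",
    "cell_mean_ar",
    "classify_cell",
    "summarize_classes",
]

CLASS_NAMES = ("Elongated", "Fragmented", "Hyperfused", "Collapsed", "Intermediate")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the rule-based network classifier.

    ``tubular_ar_min`` separates tubular from round objects; the 90%
    majority rule (``class_fraction``) follows the classical definition
    of the Elongated and Fragmented categories.  The Hyperfused and
    Collapsed criteria operationalize qualitative phenotypes (reticular
    interconnection, perinuclear clumping) and are exposed here because
    they are judgement calls, not measurements from first principles.
    """

    tubular_ar_min: float = 2.0
    class_fraction: float = 0.9
    hyperfused_component_fraction: float = 0.75
    hyperfused_max_solidity: float = 0.5
    collapsed_radius_fraction: float = 0.15
    collapsed_area_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "class_fraction",
            "hyperfused_component_fraction",
            "hyperfused_max_solidity",
            "collapsed_radius_fraction",
            "collapsed_area_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.tubular_ar_min <= 1:
            raise ValueError("tubular_ar_min must exceed 1")


@dataclass(frozen=True)
class CellMorphology:
    """Classification of one cell plus the fractions that support it."""

    cell_id: str
    morphology_class: str
    tubular_fraction: float
    largest_component_fraction: float
    clumping_index: float
    mean_ar: float


def cell_mean_ar(objects: list[MitoObject]) -> float:
    """Unweighted mean aspect ratio over a cell's mitochondria."""
    if not objects:
        raise ValueError("cannot compute mean AR of an empty object list")
    return float(np.mean([o.aspect_ratio for o in objects]))


def classify_cell(
    objects: list[MitoObject],
    label_map: np.ndarray,
    params: ClassificationParams = ClassificationParams(),
    cell_id: str = "",
) -> CellMorphology:
    """Assign a network-morphology class to one segmented cell."""
    if not objects:
        raise ValueError(f"cell {cell_id!r} has no segmented mitochondria")
    label_map = np.asarray(label_map)

    ars = np.array([o.aspect_ratio for o in objects])
    areas = np.array([o.area_px for o in objects])
    total_area = areas.sum()
    tubular = ars >= params.tubular_ar_min
    tubular_fraction = float(tubular.mean())
    largest = int(np.argmax(areas))
    largest_fraction = float(areas[largest] / total_area)

    # clumping: fraction of mitochondrial area near the area centroid,
    # radius expressed as a fraction of the image (cell crop) diagonal
    fg = np.nonzero(label_map)
    centroid = np.array([fg[0].mean(), fg[1].mean()])
    diag = float(np.hypot(*label_map.shape))
    dist = np.hypot(fg[0] - centroid[0], fg[1] - centroid[1])
    clumping_index = float(np.mean(dist <= params.collapsed_radius_fraction * diag))

    # reticular test for the dominant component: tubular by AR, or sparse
    # within its convex hull (a branched net has low solidity)
    largest_label = objects[largest].label
    largest_solidity = next(
        p.solidity for p in regionprops((label_map == largest_label).astype(np.uint8))
    )
    largest_is_reticular = (
        ars[largest] >= params.tubular_ar_min
        or largest_solidity <= params.hyperfused_max_solidity
    )

    if clumping_index >= params.collapsed_area_fraction:
        cls = "Collapsed"
    elif largest_fraction >= params.hyperfused_component_fraction and largest_is_reticular:
        cls = "Hyperfused"
    elif tubular_fraction > params.class_fraction:
        cls = "Elongated"
    elif (1.0 - tubular_fraction) > params.class_fraction:
        cls = "Fragmented"
    else:
        cls = "Intermediate"

    return CellMorphology(
        cell_id=cell_id,
        morphology_class=cls,
        tubular_fraction=tubular_fraction,
        largest_component_fraction=largest_fraction,
        clumping_index=clumping_index,
        mean_ar=cell_mean_ar(objects),
    )


def summarize_classes(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-condition class percentages with SEM across replicates.

    ``cells`` needs columns ``condition``, ``replicate`` and
    ``morphology_class``.  Within each replicate the class percentages
    sum to 100; the summary reports, per condition and class, the mean
    percentage across replicates and its standard error
    (sd / sqrt(n_replicates); 0 for a single replicate).
    """
    required = {"condition", "replicate", "morphology_class"}
    if missing := required - set(cells.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if cells.empty:
        raise ValueError("no cells to summarize")

    rows = []
    for (cond, rep), grp in cells.groupby(["condition", "replicate"]):
        n = len(grp)
        if n == 0:
            raise ValueError(f"condition {cond!r} replicate {rep!r} has no cells")
        counts = grp["morphology_class"].value_counts()
        for cls in CLASS_NAMES:
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "morphology_class": cls,
                    "percent": 100.0 * counts.get(cls, 0) / n,
                }
            )
    per_rep = pd.DataFrame(rows)

    def _sem(x: pd.Series) -> float:
        if len(x) < 2:
            return 0.0
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    out = (
        per_rep.groupby(["condition", "morphology_class"], sort=False)["percent"]
        .agg(mean_percent="mean", sem_percent=_sem, n_replicates="size")
        .reset_index()
    )
    return out
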