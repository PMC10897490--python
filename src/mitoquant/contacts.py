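"""ER-mitochondria contact-site geometry from traced annotations.

Works entirely in physical nanometres on hand-traced geometry:
mitochondrial outlines as closed polygons, ER tubules as open polylines.
An ER run lying within ``max_gap_nm`` (60 nm by convention) of its
nearest mitochondrial surface is one contact site; each contact carries
an arc length, a GAP (mean point-to-surface distance over the run), a
GAP bin ([0,15), [15,30), [30,60] nm), and the interval(s) of
mitochondrial perimeter it projects onto.  Per-cell summaries report
contacts per mitochondrion, mean contact length, mean perimeter, and the
percentage of total perimeter covered by the union of projected arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "AnnotatedScene",
    "ContactSite",
    "ContactSummary",
    "GAP_BINS",
    "sample_distances",
    "extract_contacts",
    "bin_gaps",
    "summarize",
]

GAP_BINS = ("0-15", "15-30", "30-60")


@dataclass(frozen=True)
class AnnotatedScene:
    """Traced geometry of one cell, coordinates in nm."""

    mito_polygons: list[np.ndarray]  # each (N, 2), closed implicitly
    er_polylines: list[np.ndarray]   # each (N, 2), open
    cell_id: str = ""

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.mito_polygons):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                raise ValueError(f"mito polygon {i} is not an (N>=3, 2) array")
            if not np.isfinite(arr).all():
                raise ValueError(f"mito polygon {i} has non-finite coordinates")
            if not Polygon(arr).is_valid:
                raise ValueError(f"mito polygon {i} is not a simple polygon")
        for i, line in enumerate(self.er_polylines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
                raise ValueError(f"ER polyline {i} is not an (N>=2, 2) array")
            if not np.isfinite(arr).all():
                raise ValueError(f"ER polyline {i} has non-finite coordinates")


@dataclass(frozen=True)
class ContactSite:
    """One contiguous ER-mitochondria apposition."""

    contact_id: int
    er_id: int
    mito_id: int
    length_nm: float
    gap_nm: float
    gap_bin: str
    projected_arcs: tuple[tuple[float, float], ...]  # intervals of perimeter arc position


@dataclass(frozen=True)
class ContactSummary:
    cell_id: str
    n_mito: int
    n_contacts: int
    contacts_per_mito: float
    mean_contact_length_nm: float
    mean_mito_perimeter_nm: float
    percent_perimeter_covered: float


def _bin_of(gap: float) -> str:
    # half-open on the left; the printed ranges share endpoints, so 15 nm
    # falls in 15-30 and 30 nm in 30-60; 60 nm closes the last bin
    if gap < 15:
        return GAP_BINS[0]
    if gap < 30:
        return GAP_BINS[1]
    if gap <= 60:
        return GAP_BINS[2]
    raise ValueError(f"gap {gap} nm exceeds the 60 nm contact threshold")


def sample_distances(
    er_polyline: np.ndarray,
    mito_polygons: Sequence[np.ndarray],
    step_nm: float = 5.0,
) -> pd.DataFrame:
    """Resample an ER trace and measure distance to the nearest surface.

    The polyline is resampled at uniform arc-length steps (both endpoints
    included); each sample gets its Euclidean distance to the nearest
    mitochondrial boundary (0 if it falls inside a mitochondrion) and the
    index of that mitochondrion.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if not len(mito_polygons):
        raise ValueError("scene has no mitochondria")
    line = LineString(np.asarray(er_polyline, dtype=float))
    total = line.length
    n = max(2, int(round(total / step_nm)) + 1)
    arc = np.linspace(0.0, total, n)
    pts = shapely.line_interpolate_point(line, arc)

    dists = np.empty((len(mito_polygons), n))
    for i, poly_arr in enumerate(mito_polygons):
        poly = Polygon(np.asarray(poly_arr, dtype=float))
        d = shapely.distance(pts, poly.exterior)
        inside = shapely.contains(poly, pts)
        d[inside] = 0.0
        dists[i] = d
    nearest = dists.argmin(axis=0)
    return pd.DataFrame(
        {
            "arc_nm": arc,
            "distance_nm": dists[nearest, np.arange(n)],
            "nearest_mito": nearest,
        }
    )


def _project_runs(
    samples: pd.DataFrame, run_idx: np.ndarray, er_polyline: np.ndarray,
    mito_polygon: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """Project a contact run onto the mitochondrial perimeter.

    Each sample maps to its nearest perimeter point (as an arc position
    along the outline); consecutive samples of the run span perimeter
    intervals, split where they cross the ring origin.
    """
    ring = Polygon(np.asarray(mito_polygon, dtype=float)).exterior
    perim = ring.length
    line = LineString(np.asarray(er_polyline, dtype=float))
    pos = np.array(
        [ring.project(line.interpolate(a)) for a in samples["arc_nm"].values[run_idx]]
    )
    intervals: list[tuple[float, float]] = []
    for a, b in zip(pos[:-1], pos[1:]):
        lo, hi = (a, b) if a <= b else (b, a)
        if hi - lo <= perim / 2:
            intervals.append((lo, hi))
        else:  # short way wraps through the origin
            intervals.append((0.0, lo))
            intervals.append((hi, perim))
    if not intervals:  # single-sample run: degenerate point interval
        intervals.append((pos[0], pos[0]))
    return tuple(intervals)


def extract_contacts(
    scene: AnnotatedScene,
    step_nm: float = 5.0,
    max_gap_nm: float = 60.0,
    gap_reduction: Literal["mean", "min"] = "mean",
) -> list[ContactSite]:
    """Find all contact sites of a scene.

    Maximal contiguous runs of ER samples with distance <= ``max_gap_nm``
    and a constant nearest mitochondrion become one contact each; a run's
    length is its arc extent along the ER trace and its GAP the mean (or
    minimum) sampled distance.
    """
    contacts: list[ContactSite] = []
    cid = 0
    for er_id, polyline in enumerate(scene.er_polylines):
        samples = sample_distances(polyline, scene.mito_polygons, step_nm)
        near = (samples["distance_nm"].values <= max_gap_nm)
        mito = samples["nearest_mito"].values
        arc = samples["arc_nm"].values
        i = 0
        n = len(samples)
        while i < n:
            if not near[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and near[j + 1] and mito[j + 1] == mito[i]:
                j += 1
            run = np.arange(i, j + 1)
            d = samples["distance_nm"].values[run]
            gap = float(d.mean() if gap_reduction == "mean" else d.min())
            length = float(arc[j] - arc[i]) if j > i else float(step_nm)
            contacts.append(
                ContactSite(
                    contact_id=cid,
                    er_id=er_id,
                    mito_id=int(mito[i]),
                    length_nm=length,
                    gap_nm=gap,
                    gap_bin=_bin_of(gap),
                    projected_arcs=_project_runs(
                        samples, run, polyline, scene.mito_polygons[int(mito[i])]
                    ),
                )
            )
            cid += 1
            i = j + 1
    return contacts


def bin_gaps(contacts: Sequence[ContactSite]) -> dict[str, int]:
    """Count contacts per GAP bin; the three bins partition [0, 60]."""
    counts = {b: 0 for b in GAP_BINS}
    for c in contacts:
        counts[_bin_of(c.gap_nm)] += 1
    return counts


def _union_length(intervals: list[tuple[float, float]]) -> float:
    if not intervals:
        return 0.0
    merged_len = 0.0
    intervals = sorted(intervals)
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            merged_len += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    return merged_len + (cur_hi - cur_lo)


def summarize(contacts: Sequence[ContactSite], scene: AnnotatedScene) -> ContactSummary:
    """Per-cell contact statistics.

    Coverage divides the union of projected arcs (so overlapping ER
    traces are not double-counted) by the total mitochondrial perimeter.
    """
    if not scene.mito_polygons:
        raise ValueError("scene has no mitochondria")
    perimeters = [Polygon(np.asarray(p, dtype=float)).exterior.length for p in scene.mito_polygons]
    by_mito: dict[int, list[tuple[float, float]]] = {}
    for c in contacts:
        by_mito.setdefault(c.mito_id, []).extend(c.projected_arcs)
    covered = sum(_union_length(iv) for iv in by_mito.values())
    total_perim = float(sum(perimeters))
    return ContactSummary(
        cell_id=scene.cell_id,
        n_mito=len(scene.mito_polygons),
        n_contacts=len(contacts),
        contacts_per_mito=len(contacts) / len(scene.mito_polygons),
        mean_contact_length_nm=float(np.mean([c.length_nm for c in contacts])) if contacts else 0.0,
        mean_mito_perimeter_nm=total_perim / len(perimeters),
        percent_perimeter_covered=100.0 * covered / total_perim,
    )
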