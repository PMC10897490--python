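"""Ground-truthed synthetic fixtures for all four imaging modalities.

No raw microscopy accompanies the quantification procedures implemented
here, so every analysis stage is exercised against generated scenes whose
ground truth is known by construction:

* :func:`gen_morphology_image` — a cell as a mixture of round blobs and
  curved constant-width tubules (optionally hyperfused into one reticular
  component, or collapsed into a perinuclear clump), rendered with a
  Gaussian PSF and Poisson + Gaussian noise.
* :func:`gen_timelapse` — a two-channel time-lapse in which bright foci
  tether pairs of mitochondria for programmed dwell times and each event
  ends in fusion (the pair merges) or separation.
* :func:`gen_em_scene` — traced EM-style geometry: mitochondrial outlines
  as polygons and ER tubules as polylines at controlled stand-off
  distances, in physical nanometres.
* :func:`gen_pagfp_series` — photoactivated-GFP frames spreading through
  a mitochondrial component of known area.

Identical spec + seed gives bit-identical output for every generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .contacts import AnnotatedScene
from .segmentation import moment_axes

__all__ = [
    "PlacementError",
    "MorphologySpec",
    "MorphologySample",
    "gen_morphology_image",
    "TimelapseSpec",
    "TimelapseSample",
    "gen_timelapse",
    "EMSceneSpec",
    "EMSample",
    "gen_em_scene",
    "PAGFPSpec",
    "PAGFPSample",
    "gen_pagfp_series",
]


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap within bounded retries."""


# --------------------------------------------------------------------------
# shared rendering helpers
# --------------------------------------------------------------------------


def _stamp_discs(mask: np.ndarray, rows: np.ndarray, cols: np.ndarray, radius: float) -> None:
    """Paint discs of ``radius`` at the given centres into a boolean mask."""
    h, w = mask.shape
    for rc, cc in zip(rows, cols):
        r0, r1 = int(np.floor(rc - radius)), int(np.ceil(rc + radius)) + 1
        c0, c1 = int(np.floor(cc - radius)), int(np.ceil(cc + radius)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc_grid = np.mgrid[r0:r1, c0:c1]
        mask[r0:r1, c0:c1] |= (rr - rc) ** 2 + (cc_grid - cc) ** 2 <= radius**2


def _bezier_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    return pts[:, 0], pts[:, 1]


def _tubule_mask(length: float, width: float, bow: float, angle: float, patch: int) -> np.ndarray:
    """Constant-width tube along a quadratic Bezier path, in a local patch.

    ``bow`` is the perpendicular offset of the control point; it is kept
    small relative to the length so the second-moment aspect ratio stays
    close to the straight-tube value.
    """
    c = patch / 2.0
    d = np.array([np.cos(angle), np.sin(angle)])
    perp = np.array([-d[1], d[0]])
    p0 = np.array([c, c]) - d * length / 2
    p2 = np.array([c, c]) + d * length / 2
    p1 = np.array([c, c]) + perp * bow
    n = max(8, int(np.ceil(length * 3)))
    rows, cols = _bezier_points(p0, p1, p2, n)
    mask = np.zeros((patch, patch), dtype=bool)
    _stamp_discs(mask, rows, cols, width / 2.0)
    return mask


def _apply_noise(clean: np.ndarray, psf_sigma: float, gaussian_sd: float,
                 poisson_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian PSF blur, Poisson shot noise, then Gaussian read noise."""
    img = clean.astype(np.float64)
    if psf_sigma > 0:
        img = ndimage.gaussian_filter(img, psf_sigma)
    if poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, img.shape)
    return np.clip(img, 0.0, None)


# --------------------------------------------------------------------------
# morphology images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphologySpec:
    """Composition of one synthetic cell's mitochondrial network.

    ``tubule_length_px`` is a (mean, sd) pair for a truncated normal;
    lengths are floored at twice the tubule width.  ``hyperfused`` merges
    the tubules into one star-shaped reticular component; ``collapsed``
    confines all objects to a disc of radius 0.15 x image width around a
    central focus, emulating perinuclear clumping.
    """

    n_tubules: int = 10
    n_blobs: int = 10
    tubule_length_px: tuple[float, float] = (40.0, 8.0)
    tubule_width_px: float = 4.0
    blob_radius_px: float = 5.0
    image_size_px: tuple[int, int] = (256, 256)
    psf_sigma_px: float = 1.0
    gaussian_sd: float = 2.0
    poisson_scale: float = 0.5
    amplitude: float = 200.0
    hyperfused: bool = False
    collapsed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tubules < 0 or self.n_blobs < 0:
            raise ValueError("object counts must be non-negative")
        if min(self.tubule_width_px, self.blob_radius_px, self.tubule_length_px[0]) <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.psf_sigma_px < 0 or self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class MorphologySample:
    """A rendered cell plus its ground truth."""

    image: np.ndarray        # noisy intensity image (H, W)
    labels: np.ndarray       # noise-free ground-truth label map
    objects: pd.DataFrame    # per-object truth: kind, position, size, true AR
    true_class: str


def _true_class(spec: MorphologySpec) -> str:
    if spec.collapsed:
        return "Collapsed"
    if spec.hyperfused:
        return "Hyperfused"
    n = spec.n_tubules + spec.n_blobs
    if n == 0:
        return "Intermediate"
    tf = spec.n_tubules / n
    if tf > 0.9:
        return "Elongated"
    if tf < 0.1:
        return "Fragmented"
    return "Intermediate"


def _place(labels: np.ndarray, patch: np.ndarray, rng: np.random.Generator,
           label: int, center: tuple[float, float] | None = None,
           max_radius: float | None = None, margin: int = 4,
           retries: int = 200) -> tuple[int, int]:
    """Drop a patch mask into the label map without touching anything.

    Placement is rejected if the patch (dilated by 3 px, so objects keep
    a >= 4 px clearance and never merge under the PSF) intersects
    existing foreground or the image border.  ``center``/``max_radius``
    restrict candidate positions to a disc (collapsed phenotype).
    """
    h, w = labels.shape
    ph, pw = patch.shape
    pad = 5
    grown = ndimage.binary_dilation(np.pad(patch, pad), structure=np.ones((9, 9), dtype=bool))
    for _ in range(retries):
        if center is not None and max_radius is not None:
            ang = rng.uniform(0, 2 * np.pi)
            rad = max_radius * np.sqrt(rng.uniform())
            r0 = int(center[0] + rad * np.sin(ang) - ph / 2)
            c0 = int(center[1] + rad * np.cos(ang) - pw / 2)
        else:
            r0 = int(rng.uniform(margin, h - ph - margin))
            c0 = int(rng.uniform(margin, w - pw - margin))
        if r0 < max(margin, pad) or c0 < max(margin, pad):
            continue
        if r0 + ph > h - max(margin, pad) or c0 + pw > w - max(margin, pad):
            continue
        if (labels[r0 - pad : r0 + ph + pad, c0 - pad : c0 + pw + pad][grown] != 0).any():
            continue
        labels[r0 : r0 + ph, c0 : c0 + pw][patch] = label
        return r0, c0
    raise PlacementError(f"could not place object {label} after {retries} attempts")


def _object_row(labels: np.ndarray, label: int, kind: str, **extra) -> dict:
    rows, cols = np.nonzero(labels == label)
    major, minor = moment_axes(rows, cols)
    return {
        "object_id": label,
        "kind": kind,
        "centroid_row": rows.mean(),
        "centroid_col": cols.mean(),
        "area_px": rows.size,
        "true_ar": major / minor,
        **extra,
    }


def gen_morphology_image(spec: MorphologySpec) -> MorphologySample:
    """Render one cell and return it with per-object ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    labels = np.zeros((h, w), dtype=np.int32)
    records: list[dict] = []
    next_label = 1

    if spec.hyperfused:
        # star-shaped reticular net: tubule arms radiating from the centre,
        # one connected component holding most of the mitochondrial area
        n_arms = max(6, spec.n_tubules)
        arm_len = 0.40 * min(h, w)
        cr, cc = h / 2.0, w / 2.0
        net = np.zeros((h, w), dtype=bool)
        for i in range(n_arms):
            ang = 2 * np.pi * i / n_arms + rng.normal(0, 0.08)
            length = arm_len * rng.uniform(0.85, 1.0)
            t = np.linspace(0, 1, int(length * 3))
            rows = cr + t * length * np.sin(ang)
            cols = cc + t * length * np.cos(ang)
            _stamp_discs(net, rows, cols, spec.tubule_width_px / 2)
        labels[net] = next_label
        records.append(_object_row(labels, next_label, "network"))
        next_label += 1
        for _ in range(min(spec.n_blobs, 4)):  # a few peripheral fragments
            patch_sz = int(2 * spec.blob_radius_px + 4)
            patch = np.zeros((patch_sz, patch_sz), dtype=bool)
            _stamp_discs(patch, np.array([patch_sz / 2]), np.array([patch_sz / 2]), spec.blob_radius_px)
            _place(labels, patch, rng, next_label)
            records.append(_object_row(labels, next_label, "blob", radius_px=spec.blob_radius_px))
            next_label += 1
    else:
        center = (h / 2.0, w / 2.0) if spec.collapsed else None
        max_radius = 0.15 * w if spec.collapsed else None
        kinds = ["tubule"] * spec.n_tubules + ["blob"] * spec.n_blobs
        rng.shuffle(kinds)
        for kind in kinds:
            if kind == "tubule":
                mu, sd = spec.tubule_length_px
                length = max(2 * spec.tubule_width_px, rng.normal(mu, sd))
                if spec.collapsed:
                    length = min(length, 0.2 * w)
                bow = rng.uniform(-0.04, 0.04) * length
                angle = rng.uniform(0, np.pi)
                patch_sz = int(length + spec.tubule_width_px + 6)
                patch = _tubule_mask(length, spec.tubule_width_px, bow, angle, patch_sz)
                _place(labels, patch, rng, next_label, center, max_radius)
                records.append(
                    _object_row(labels, next_label, "tubule",
                                length_px=length, width_px=spec.tubule_width_px,
                                bow_px=bow, angle_rad=angle)
                )
            else:
                patch_sz = int(2 * spec.blob_radius_px + 4)
                patch = np.zeros((patch_sz, patch_sz), dtype=bool)
                _stamp_discs(patch, np.array([patch_sz / 2]), np.array([patch_sz / 2]), spec.blob_radius_px)
                _place(labels, patch, rng, next_label, center, max_radius)
                records.append(_object_row(labels, next_label, "blob", radius_px=spec.blob_radius_px))
            next_label += 1

    clean = spec.amplitude * (labels > 0).astype(np.float64)
    image = _apply_noise(clean, spec.psf_sigma_px, spec.gaussian_sd, spec.poisson_scale, rng)
    objects = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["object_id", "kind", "centroid_row", "centroid_col", "area_px", "true_ar"]
    )
    return MorphologySample(image=image, labels=labels, objects=objects,
                            true_class=_true_class(spec))


# --------------------------------------------------------------------------
# tethering time-lapse
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TimelapseSpec:
    """Two-channel time-lapse with programmed tethering events.

    Each event owns one site in a grid: a pair of capsule-shaped
    mitochondria facing each other across a small gap, with a bright
    focus at the junction for the drawn dwell time.  Dwell times come
    from ``dwell_dist``: ``("point", value)`` or
    ``("shifted_exponential", loc, scale)``; they are rounded to the
    frame interval.  With probability ``p_fusion`` the event ends with
    the pair merging (a bridge is drawn from the merge frame onward);
    otherwise the capsules drift apart.
    """

    n_frames: int = 100
    dt_s: float = 3.0
    n_events: int = 5
    dwell_dist: tuple = ("point", 30.0)
    p_fusion: float = 0.5
    foci_intensity: float = 150.0
    mito_intensity: float = 120.0
    capsule_length_px: float = 16.0
    capsule_width_px: float = 5.0
    gap_px: float = 3.0
    site_size_px: int = 52
    jitter_sd_px: float = 0.5
    spot_sigma_px: float = 1.5
    gaussian_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_fusion <= 1:
            raise ValueError("p_fusion must be in [0, 1]")
        if self.dt_s <= 0 or self.n_frames < 2:
            raise ValueError("need dt_s > 0 and at least two frames")


@dataclass(frozen=True)
class TimelapseSample:
    stack: np.ndarray     # (T, 2, H, W); channel 0 = foci, channel 1 = mitochondria
    events: pd.DataFrame  # truth: start/end frame, duration_s, outcome, junction


def _draw_dwell(dist: tuple, rng: np.random.Generator) -> float:
    name = dist[0]
    if name == "point":
        return float(dist[1])
    if name == "shifted_exponential":
        loc, scale = float(dist[1]), float(dist[2])
        return loc + rng.exponential(scale)
    raise ValueError(f"unknown dwell distribution {name!r}")


def _capsule(mask: np.ndarray, r: float, c0: float, c1: float, width: float) -> None:
    """Stamp a horizontal capsule whose full extent is [c0, c1]."""
    rad = width / 2
    lo, hi = min(c0, c1) + rad, max(c0, c1) - rad
    hi = max(hi, lo)
    n = max(4, int((hi - lo) * 3))
    cols = np.linspace(lo, hi, n)
    _stamp_discs(mask, np.full(n, r), cols, rad)


def gen_timelapse(spec: TimelapseSpec) -> TimelapseSample:
    """Render the stack and the true event table."""
    rng = np.random.default_rng(spec.seed)
    grid = int(np.ceil(np.sqrt(max(spec.n_events, 1))))
    s = spec.site_size_px
    h = w = grid * s
    half_gap = spec.gap_px / 2
    cap_l, cap_w = spec.capsule_length_px, spec.capsule_width_px

    # per-site patches for the three mitochondrial states
    def _pair(gap_half: float, bridged: bool) -> np.ndarray:
        m = np.zeros((s, s), dtype=bool)
        r = s / 2.0
        _capsule(m, r, s / 2 - gap_half - cap_l, s / 2 - gap_half, cap_w)
        _capsule(m, r, s / 2 + gap_half, s / 2 + gap_half + cap_l, cap_w)
        if bridged:
            _capsule(m, r, s / 2 - gap_half, s / 2 + gap_half, cap_w)
        return m

    # patches are blurred once here (PSF sigma 0.5) instead of per frame
    tethered, separated, fused = (
        ndimage.gaussian_filter(m.astype(np.float64), 0.5)
        for m in (_pair(half_gap, False), _pair(half_gap + 3.0, False), _pair(half_gap, True))
    )

    # schedule events: dwell -> whole frames; must resolve before the end
    records = []
    max_total = spec.n_frames - 4  # leave room for outcome confirmation
    for e in range(spec.n_events):
        # a finite movie cannot contain arbitrarily long complete events;
        # dwells beyond the window are redrawn (right-truncation), and a
        # distribution that can never fit is an error
        for _ in range(1000):
            dwell = _draw_dwell(spec.dwell_dist, rng)
            k = max(1, int(round(dwell / spec.dt_s)))
            if k <= max_total - 1:
                break
        else:
            raise ValueError(
                f"event dwell {dwell:.0f}s ({k} frames) does not fit in "
                f"{spec.n_frames} frames of {spec.dt_s}s"
            )
        start = int(rng.integers(0, max_total - k))
        outcome = "fused" if rng.uniform() < spec.p_fusion else "separated"
        site_r, site_c = divmod(e, grid)
        records.append(
            {
                "event_id": e,
                "start_frame": start,
                "end_frame": start + k,
                "duration_s": k * spec.dt_s,
                "outcome": outcome,
                "junction_row": site_r * s + s / 2.0,
                "junction_col": site_c * s + s / 2.0,
            }
        )
    events = pd.DataFrame(records)

    stack = np.zeros((spec.n_frames, 2, h, w), dtype=np.float64)
    for t in range(spec.n_frames):
        mito = np.zeros((h, w), dtype=np.float64)
        foci = np.zeros((h, w), dtype=np.float64)
        for rec in records:
            site_r = int(rec["junction_row"] - s / 2)
            site_c = int(rec["junction_col"] - s / 2)
            if rec["outcome"] == "fused":
                patch = fused if t >= rec["end_frame"] else tethered
            else:
                patch = tethered if t <= rec["end_frame"] else separated
            mito[site_r : site_r + s, site_c : site_c + s] = spec.mito_intensity * patch
            if rec["start_frame"] <= t <= rec["end_frame"]:
                jr = rec["junction_row"] + rng.normal(0, spec.jitter_sd_px)
                jc = rec["junction_col"] + rng.normal(0, spec.jitter_sd_px)
                rr, cc = np.mgrid[0:h, 0:w][:, int(jr) - 6 : int(jr) + 7, int(jc) - 6 : int(jc) + 7]
                g = np.exp(-((rr - jr) ** 2 + (cc - jc) ** 2) / (2 * spec.spot_sigma_px**2))
                foci[int(jr) - 6 : int(jr) + 7, int(jc) - 6 : int(jc) + 7] += spec.foci_intensity * g
        stack[t, 0] = _apply_noise(foci, 0.0, spec.gaussian_sd, 0.0, rng)
        stack[t, 1] = _apply_noise(mito, 0.0, spec.gaussian_sd, 0.0, rng)
    return TimelapseSample(stack=stack, events=events)


# --------------------------------------------------------------------------
# EM scenes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EMSceneSpec:
    """Traced EM geometry with programmed ER stand-off distances.

    ``er_segments`` is a list of ``(target, standoff_nm, arc_length_nm)``
    tuples.  A segment with an integer target is drawn as an arc
    concentric with that mitochondrion at the given stand-off; a segment
    with target ``None`` is a straight tubule placed far (> 100 nm) from
    every mitochondrion.  Segments with stand-off <= 60 nm enter the
    ground-truth contact table; the rest appear only in the scene.
    """

    n_mito: int = 2
    mito_radius_nm: float = 400.0
    er_segments: Sequence[tuple[int | None, float, float]] = ((0, 20.0, 400.0),)
    nm_per_unit: float = 1.0
    n_vertices: int = 720
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mito < 1 or self.mito_radius_nm <= 0:
            raise ValueError("need at least one mitochondrion of positive radius")
        for tgt, standoff, length in self.er_segments:
            if standoff < 0 or length <= 0:
                raise ValueError("stand-off must be >= 0 and arc length > 0")
            if tgt is not None and not 0 <= tgt < self.n_mito:
                raise ValueError(f"ER target {tgt} out of range")


@dataclass(frozen=True)
class EMSample:
    scene: AnnotatedScene
    contacts: pd.DataFrame  # truth: er_id, mito_id, gap_nm, length_nm, gap_bin, projected_arc_nm
    summary: dict           # truth per-cell summary


def _gap_bin(gap: float) -> str:
    if gap < 15:
        return "0-15"
    if gap < 30:
        return "15-30"
    return "30-60"


def gen_em_scene(spec: EMSceneSpec) -> EMSample:
    """Build the annotated scene and its ground-truth contact table."""
    rng = np.random.default_rng(spec.seed)
    R = spec.mito_radius_nm
    spacing = 4 * (R + 150)
    grid = int(np.ceil(np.sqrt(spec.n_mito)))
    centers = [
        np.array([spacing * (i // grid), spacing * (i % grid)], dtype=float)
        for i in range(spec.n_mito)
    ]

    ang = np.linspace(0, 2 * np.pi, spec.n_vertices, endpoint=False)
    polygons = [
        np.column_stack([c[0] + R * np.cos(ang), c[1] + R * np.sin(ang)])
        for c in centers
    ]
    # perimeter of the discretised outline (what the analysis will measure)
    perimeter = spec.n_vertices * 2 * R * np.sin(np.pi / spec.n_vertices)

    used: dict[int, list[tuple[float, float]]] = {i: [] for i in range(spec.n_mito)}
    margin_rad = 0.25
    polylines: list[np.ndarray] = []
    truth = []
    for er_id, (tgt, standoff, length) in enumerate(spec.er_segments):
        if tgt is None:
            # free tubule in empty space, well beyond the contact threshold
            base = np.array([-spacing, -spacing]) - er_id * np.array([0.0, length + 200])
            n = max(8, int(round(length / 4)) + 1)
            xs = np.linspace(0, length, n)
            polylines.append(np.column_stack([base[0] + xs, np.full(n, base[1])]))
            continue
        r_er = R + standoff
        theta = length / r_er
        placed = False
        for _ in range(200):
            a0 = rng.uniform(0, 2 * np.pi)
            if a0 + theta + margin_rad > 2 * np.pi:
                continue
            if all(a0 + theta + margin_rad < lo or a0 > hi + margin_rad for lo, hi in used[tgt]):
                placed = True
                break
        if not placed:
            raise PlacementError(f"no free angular range for ER segment {er_id}")
        used[tgt].append((a0, a0 + theta))
        n = max(8, int(round(length / 4)) + 1)
        a = np.linspace(a0, a0 + theta, n)
        c = centers[tgt]
        poly = np.column_stack([c[0] + r_er * np.cos(a), c[1] + r_er * np.sin(a)])
        polylines.append(poly)
        if standoff <= 60:
            chord_len = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
            truth.append(
                {
                    "er_id": er_id,
                    "mito_id": tgt,
                    "gap_nm": standoff,
                    "length_nm": chord_len,
                    "gap_bin": _gap_bin(standoff),
                    "projected_arc_nm": theta * perimeter / (2 * np.pi),
                }
            )

    contacts = pd.DataFrame(
        truth,
        columns=["er_id", "mito_id", "gap_nm", "length_nm", "gap_bin", "projected_arc_nm"],
    )
    summary = {
        "n_contacts": len(contacts),
        "contacts_per_mito": len(contacts) / spec.n_mito,
        "mean_contact_length_nm": float(contacts["length_nm"].mean()) if len(contacts) else 0.0,
        "mean_mito_perimeter_nm": float(perimeter),
        "percent_perimeter_covered": 100.0
        * float(contacts["projected_arc_nm"].sum()) / (spec.n_mito * perimeter),
    }
    scene = AnnotatedScene(
        mito_polygons=[p * spec.nm_per_unit for p in polygons],
        er_polylines=[p * spec.nm_per_unit for p in polylines],
        cell_id="synthetic",
    )
    return EMSample(scene=scene, contacts=contacts, summary=summary)


# --------------------------------------------------------------------------
# PA-GFP spread series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PAGFPSpec:
    """Photoactivation series over components of known area.

    Mitochondrial components are rendered as horizontal bars; activation
    starts in the leftmost ``roi_fraction`` of the activated bar and the
    GFP-positive region grows to ``spread_fractions[k]`` of the bar at
    each timepoint (content mixing never crosses components).
    """

    component_areas_px: Sequence[float] = (1200.0, 800.0, 600.0)
    activated_component: int = 0
    roi_fraction: float = 0.2
    timepoints_min: Sequence[float] = (0.0, 5.0, 10.0)
    spread_fractions: Sequence[float] = (0.2, 0.6, 1.0)
    bar_height_px: int = 12
    intensity: float = 150.0
    psf_sigma_px: float = 0.5
    gaussian_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.activated_component < len(self.component_areas_px):
            raise ValueError("activated_component out of range")
        sf = np.asarray(self.spread_fractions, dtype=float)
        if len(sf) != len(self.timepoints_min):
            raise ValueError("spread_fractions and timepoints_min lengths differ")
        if np.any(np.diff(sf) < 0):
            raise ValueError("spread_fractions must be non-decreasing")
        if not np.isclose(sf[0], self.roi_fraction):
            raise ValueError("spread_fractions[0] must equal roi_fraction")
        if not 0 < self.roi_fraction <= 1 or np.any(sf <= 0) or np.any(sf > 1):
            raise ValueError("fractions must lie in (0, 1]")


@dataclass(frozen=True)
class PAGFPSample:
    mito_mask: np.ndarray           # bool (H, W)
    frames: np.ndarray              # (T, H, W) GFP channel
    roi: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    timepoints_min: np.ndarray
    true_normalized_area: np.ndarray


def gen_pagfp_series(spec: PAGFPSpec) -> PAGFPSample:
    """Render mito mask, ROI, and GFP frames; truth from pixel counts."""
    rng = np.random.default_rng(spec.seed)
    hbar = spec.bar_height_px
    widths = [max(4, int(round(a / hbar))) for a in spec.component_areas_px]
    margin = 10
    h = margin + len(widths) * (hbar + margin)
    w = 2 * margin + max(widths)
    mask = np.zeros((h, w), dtype=bool)
    bars = []
    for i, bw in enumerate(widths):
        r0 = margin + i * (hbar + margin)
        mask[r0 : r0 + hbar, margin : margin + bw] = True
        bars.append((r0, r0 + hbar, margin, margin + bw))

    r0, r1, c0, _ = bars[spec.activated_component]
    bw = widths[spec.activated_component]
    n_cols = [max(1, int(round(f * bw))) for f in spec.spread_fractions]
    roi = (r0, r1, c0, c0 + n_cols[0])

    frames = np.zeros((len(n_cols), h, w), dtype=np.float64)
    for k, nc in enumerate(n_cols):
        clean = np.zeros((h, w), dtype=np.float64)
        clean[r0:r1, c0 : c0 + nc] = spec.intensity
        frames[k] = _apply_noise(clean, spec.psf_sigma_px, spec.gaussian_sd, 0.0, rng)

    areas = np.array([nc * hbar for nc in n_cols], dtype=float)
    return PAGFPSample(
        mito_mask=mask,
        frames=frames,
        roi=roi,
        timepoints_min=np.asarray(spec.timepoints_min, dtype=float),
        true_normalized_area=areas / areas[0],
    )
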