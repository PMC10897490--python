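"""Brute-force reference computations used to check the implementation.

Everything here is written from first principles (explicit sums, dense
sampling, exhaustive search) and deliberately shares no code path with
the package.
"""

from __future__ import annotations

import numpy as np


def moment_ar(mask: np.ndarray) -> float:
    """Aspect ratio from second central moments of the mask.

    Pixels are unit squares, so each contributes 1/12 to both diagonal
    moments on top of its centre coordinates; this makes the result for
    an axis-aligned rectangle exactly its side ratio.
    """
    rs, cs = np.nonzero(mask)
    n = rs.size
    mr, mc = rs.sum() / n, cs.sum() / n
    mrr = ((rs - mr) ** 2).sum() / n + 1.0 / 12.0
    mcc = ((cs - mc) ** 2).sum() / n + 1.0 / 12.0
    mrc = ((rs - mr) * (cs - mc)).sum() / n
    tr = mrr + mcc
    det = np.sqrt((mrr - mcc) ** 2 + 4 * mrc**2)
    lam_max, lam_min = (tr + det) / 2, (tr - det) / 2
    return float(np.sqrt(lam_max / lam_min))


def point_to_polygon_distance(point: np.ndarray, polygon: np.ndarray, n_dense: int = 20000) -> float:
    """Distance to a polygon boundary by dense edge sampling."""
    closed = np.vstack([polygon, polygon[:1]])
    pts = []
    for a, b in zip(closed[:-1], closed[1:]):
        t = np.linspace(0, 1, max(2, n_dense // len(polygon)))[:, None]
        pts.append(a + t * (b - a))
    pts = np.vstack(pts)
    return float(np.min(np.hypot(*(pts - point).T)))


def interval_union_length(intervals: list[tuple[float, float]], resolution: float = 0.01) -> float:
    """Union length by fine discretization of the covered range."""
    if not intervals:
        return 0.0
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    n = int(np.ceil((hi - lo) / resolution)) + 1
    grid = np.zeros(n, dtype=bool)
    for a, b in intervals:
        i0 = int(np.floor((a - lo) / resolution))
        i1 = int(np.ceil((b - lo) / resolution))
        grid[i0:i1] = True
    return float(grid.sum() * resolution)


def best_assignment_tracks(spots_per_frame: list[np.ndarray], max_link: float) -> int:
    """Number of tracks under exhaustive minimal-cost frame-to-frame matching.

    Only practical for a handful of spots; used to confirm the greedy
    linker on small instances.
    """
    from itertools import permutations

    tracks: list[list[tuple[float, float]]] = []
    active: list[int] = []
    for spots in spots_per_frame:
        spots = np.asarray(spots, dtype=float).reshape(-1, 2)
        best, best_cost = None, np.inf
        m, n = len(active), len(spots)
        for perm in permutations(range(n), min(m, n)):
            cost, valid, pairs = 0.0, True, []
            for ai, si in zip(range(m), perm):
                d = float(np.hypot(*(np.array(tracks[active[ai]][-1]) - spots[si])))
                if d > max_link:
                    continue
                cost += d
                pairs.append((ai, si))
            if pairs and cost / len(pairs) < best_cost:
                best, best_cost = pairs, cost / len(pairs)
        assigned = set()
        new_active = []
        if best:
            for ai, si in best:
                tracks[active[ai]].append(tuple(spots[si]))
                new_active.append(active[ai])
                assigned.add(si)
        for si in range(len(spots)):
            if si not in assigned:
                tracks.append([tuple(spots[si])])
                new_active.append(len(tracks) - 1)
        active = new_active
    return len(tracks)


def tophat_disc_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat via explicit min/max filters with a disc footprint."""
    from scipy.ndimage import maximum_filter, minimum_filter

    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = yy**2 + xx**2 <= radius**2
    opened = maximum_filter(minimum_filter(image, footprint=footprint), footprint=footprint)
    return image - opened
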