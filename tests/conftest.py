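import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from mitoquant.segmentation import SegmentationParams


@pytest.fixture
def fast_seg_params() -> SegmentationParams:
    """Segmentation defaults sized for the small synthetic test images."""
    return SegmentationParams(background_radius_px=15)


def rectangle_mask(length: float, width: float, angle_deg: float, pad: int = 20) -> np.ndarray:
    """Render a filled rotated rectangle as a boolean mask."""
    theta = np.deg2rad(angle_deg)
    half = np.array(
        [[-length / 2, -width / 2], [length / 2, -width / 2],
         [length / 2, width / 2], [-length / 2, width / 2]]
    )
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    corners = half @ rot.T
    size = int(np.ceil(max(length, width))) + 2 * pad
    # half-pixel offset so an axis-aligned L x w rectangle rasterizes to
    # exactly L x w pixel centers
    center = size // 2 + 0.5
    rr, cc = draw_polygon(corners[:, 0] + center, corners[:, 1] + center, (size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def disc_mask(radius: float, pad: int = 5) -> np.ndarray:
    size = int(2 * radius) + 2 * pad
    rr, cc = np.mgrid[0:size, 0:size]
    c = size / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
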