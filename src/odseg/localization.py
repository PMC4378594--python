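"""Optic-disc localization: template matching, Canny edges, circle Hough, ROI.

The disc is first located coarsely by Pearson correlation of the HSI
intensity channel with a bright circular template, then the center and an
estimated radius are refined by a circle Hough transform on the Canny edge
map of a 900x900 region of interest around the match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from scipy.special import erf
from skimage import feature
from skimage.draw import circle_perimeter
from skimage.transform import downscale_local_mean

log = logging.getLogger(__name__)

__all__ = [
    "TemplateSpec",
    "DiscEstimate",
    "RoiWindow",
    "LocalizationError",
    "hsi_intensity",
    "build_disc_template",
    "pearson_match",
    "canny_edges",
    "hough_circle",
    "extract_roi",
    "locate_disc",
    "DEFAULT_HOUGH_RADII",
]

#: Hough radii used for disc-sized circles: 140..230 px in steps of 15.
DEFAULT_HOUGH_RADII: tuple[int, ...] = tuple(range(140, 231, 15))


class LocalizationError(RuntimeError):
    """Raised when the disc cannot be localized (e.g. empty edge map)."""


@dataclass(frozen=True)
class TemplateSpec:
    """Bright-disc matching template: side x side, circular core, soft edge.

    The default 401x401 side suits images whose disc width lies in
    [260, 380] px; the core diameter sits at the midpoint of that range.
    """

    side: int = 401
    core_diameter: int = 320
    edge_softness: float = 40.0

    def validate(self) -> None:
        if self.side % 2 != 1:
            raise ValueError("template side must be odd")
        if not (0 < self.core_diameter < self.side):
            raise ValueError("core_diameter must be positive and smaller than side")
        if self.edge_softness <= 0:
            raise ValueError("edge_softness must be positive")


@dataclass
class DiscEstimate:
    center: tuple[int, int]  # (row, col), 0-based
    radius: float
    score: float

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")
        if shape is not None:
            r, c = self.center
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError("disc center outside image bounds")


@dataclass
class RoiWindow:
    """A side x side crop plus the bookkeeping to map back to full coords.

    ``offset`` is the crop origin in the padded image; ``pad`` the
    (top, left) edge-replication padding that was applied, so a ROI pixel
    (r, c) sits at ``(r, c) + offset - pad`` in the original image.
    """

    image: np.ndarray
    offset: tuple[int, int]
    side: int
    pad: tuple[int, int] = (0, 0)

    def to_full(self, r: float, c: float) -> tuple[float, float]:
        return (
            r + self.offset[0] - self.pad[0],
            c + self.offset[1] - self.pad[1],
        )

    def mask_to_full(self, mask: np.ndarray, full_shape: tuple[int, int]) -> np.ndarray:
        """Paste a ROI-coordinate mask into a full-image canvas."""
        out = np.zeros(full_shape, dtype=bool)
        top = self.offset[0] - self.pad[0]
        left = self.offset[1] - self.pad[1]
        r0, c0 = max(top, 0), max(left, 0)
        r1 = min(top + self.side, full_shape[0])
        c1 = min(left + self.side, full_shape[1])
        if r1 > r0 and c1 > c0:
            out[r0:r1, c0:c1] = mask[r0 - top : r1 - top, c0 - left : c1 - left]
        return out


def hsi_intensity(rgb: np.ndarray) -> np.ndarray:
    """Intensity channel of the HSI color space: I = (R + G + B) / 3."""
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return rgb.mean(axis=-1)


def build_disc_template(spec: TemplateSpec = TemplateSpec()) -> np.ndarray:
    """Radially symmetric bright-core template with an erf falloff to 0."""
    spec.validate()
    half = spec.side // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r = np.hypot(y, x)
    return 0.5 * (1.0 - erf((r - spec.core_diameter / 2.0) / spec.edge_softness))


def pearson_match(gray: np.ndarray, template: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Pearson correlation of ``template`` against every valid window.

    Returns the valid-mode score map (values in [-1, 1]; windows of zero
    variance score 0) and the (row, col) of the template *center* at the
    maximum-score placement.
    """
    if template.shape[0] > gray.shape[0] or template.shape[1] > gray.shape[1]:
        raise ValueError("template larger than image")
    if np.ptp(template) == 0:
        raise ValueError("template is constant; correlation undefined")
    scores = feature.match_template(gray.astype(np.float64), template.astype(np.float64))
    scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
    scores = np.clip(scores, -1.0, 1.0)
    i, j = np.unravel_index(np.argmax(scores), scores.shape)
    center = (i + template.shape[0] // 2, j + template.shape[1] // 2)
    return scores, center


def canny_edges(gray: np.ndarray, high_threshold: float = 0.4, *, sigma: float = 5.0, low_ratio: float = 0.4) -> np.ndarray:
    """Canny edge map with hysteresis thresholds on the *normalized* gradient.

    The image is Gaussian-smoothed (sigma px), and the high hysteresis
    threshold is ``high_threshold`` times the maximum gradient magnitude,
    so 0.4 reads "40% of the strongest edge". The low threshold is
    ``low_ratio`` times the high one.
    """
    gray = np.asarray(gray, dtype=np.float64)
    # same smoothing + Sobel pipeline Canny applies internally, to find the
    # gradient-magnitude ceiling the fractional thresholds refer to
    smoothed = ndi.gaussian_filter(gray, sigma, mode="nearest")
    gmax = float(
        np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1)).max()
    )
    if gmax <= 1e-12:
        return np.zeros(gray.shape, dtype=bool)
    return feature.canny(
        gray,
        sigma=sigma,
        low_threshold=low_ratio * high_threshold * gmax,
        high_threshold=high_threshold * gmax,
        mode="nearest",
    )


def _circle_kernel(radius: int) -> np.ndarray:
    k = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=np.float64)
    rr, cc = circle_perimeter(radius, radius, radius)
    k[rr, cc] = 1.0
    return k


def hough_circle(edges: np.ndarray, radii=DEFAULT_HOUGH_RADII) -> DiscEstimate:
    """Circle Hough transform over a list of fixed radii.

    Each edge pixel votes for every center at distance R (midpoint-circle
    rasterization). Accumulators are smoothed with a 3x3 box mean before the
    global argmax; ties break toward the smallest radius, then row-major
    scan order.
    """
    radii = sorted(set(int(r) for r in radii))
    if not radii:
        raise ValueError("radius list must be non-empty")
    edges = np.asarray(edges, dtype=bool)
    if not edges.any():
        raise LocalizationError("empty edge map: no circle evidence to accumulate")
    e = edges.astype(np.float64)
    best = None
    for r in radii:
        acc = np.rint(fftconvolve(e, _circle_kernel(r), mode="same"))
        acc = ndi.uniform_filter(acc, size=3, mode="constant")
        idx = int(np.argmax(acc))
        val = float(acc.flat[idx])
        if best is None or val > best[0]:
            best = (val, r, np.unravel_index(idx, acc.shape))
    score, radius, center = best
    return DiscEstimate(center=(int(center[0]), int(center[1])), radius=float(radius), score=score)


def extract_roi(image: np.ndarray, center: tuple[int, int], side: int = 900) -> RoiWindow:
    """Cut a side x side window centered at ``center``, edge-padding as needed."""
    r, c = int(round(center[0])), int(round(center[1]))
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError("ROI center outside the image")
    half = side // 2
    top, left = r - half, c - half
    pad_top = max(-top, 0)
    pad_left = max(-left, 0)
    pad_bottom = max(top + side - image.shape[0], 0)
    pad_right = max(left + side - image.shape[1], 0)
    if pad_top or pad_left or pad_bottom or pad_right:
        widths = [(pad_top, pad_bottom), (pad_left, pad_right)]
        if image.ndim == 3:
            widths.append((0, 0))
        image = np.pad(image, widths, mode="edge")
    top += pad_top
    left += pad_left
    crop = image[top : top + side, left : left + side]
    return RoiWindow(image=crop, offset=(top, left), side=side, pad=(pad_top, pad_left))


def locate_disc(
    rgb: np.ndarray,
    template_spec: TemplateSpec = TemplateSpec(),
    *,
    downscale: int = 4,
    refine_window: int = 64,
    roi_side: int = 900,
    canny_threshold: float = 0.4,
    canny_sigma: float = 5.0,
    radii=DEFAULT_HOUGH_RADII,
) -> tuple[DiscEstimate, tuple[int, int]]:
    """Full localization: coarse-to-fine template match, then Hough refinement.

    The Pearson match runs on a ``downscale``-times block-averaged image with
    a correspondingly shrunk template, and the argmax is refined at full
    resolution inside a ``refine_window`` px neighborhood. Canny + Hough then
    run on the ROI around the match. Returns the estimate in full-image
    coordinates together with the template-match center.
    """
    gray = hsi_intensity(rgb)
    template = build_disc_template(template_spec)

    small = downscale_local_mean(gray, (downscale, downscale))
    t_small = downscale_local_mean(template, (downscale, downscale))
    _, coarse = pearson_match(small, t_small)
    coarse_full = (coarse[0] * downscale, coarse[1] * downscale)

    # full-resolution refinement in a window around the coarse hit
    half_t = template.shape[0] // 2
    margin = half_t + refine_window
    win = extract_roi(gray, coarse_full, side=2 * margin + 1)
    _, refined = pearson_match(win.image, template)
    match_center = tuple(int(round(v)) for v in win.to_full(*refined))
    match_center = (
        int(np.clip(match_center[0], 0, gray.shape[0] - 1)),
        int(np.clip(match_center[1], 0, gray.shape[1] - 1)),
    )

    roi = extract_roi(gray, match_center, side=roi_side)
    edges = canny_edges(roi.image, canny_threshold, sigma=canny_sigma)
    est_roi = hough_circle(edges, radii)
    full_center = roi.to_full(*est_roi.center)
    estimate = DiscEstimate(
        center=(int(round(full_center[0])), int(round(full_center[1]))),
        radius=est_roi.radius,
        score=est_roi.score,
    )
    estimate.validate(gray.shape[:2])
    return estimate, match_center
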