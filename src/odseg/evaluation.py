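"""Segmentation scoring and baseline methods.

The dice coefficient DC = 2|A∩B| / (|A| + |B|) quantifies mask overlap.
Two classical baselines are provided for comparison tables: the
gradient-force snake (same contour engine, image force from the intensity
gradient, initialized at the full estimated radius as classic snakes
require) and texture clustering with an ellipse fit (2-feature fuzzy
c-means, morphological cleanup, direct least-squares ellipse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import EllipseModel, label
from skimage.morphology import closing as binary_closing, disk, opening as binary_opening

from .balloon_snake import SnakeConfig, contour_to_mask, evolve, init_circle, texture_potential
from .localization import DiscEstimate
from .noise_suppression import FcmConfig, enlarged_analysis_region, fcm
from .texture_banks import filter_bank_responses, mr8_responses, schmid_kernel

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationScore",
    "dice",
    "gradient_snake_segment",
    "fcm_texture_segment",
    "evaluate_batch",
]


@dataclass(frozen=True)
class SegmentationScore:
    dice: float
    area_truth: int
    area_pred: int
    area_intersection: int


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> SegmentationScore:
    """Dice coefficient of two binary masks.

    Both masks empty scores 1 (vacuous perfect agreement); exactly one
    empty scores 0.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    a = int(mask_a.sum())
    b = int(mask_b.sum())
    inter = int((mask_a & mask_b).sum())
    value = 1.0 if a + b == 0 else 2.0 * inter / (a + b)
    return SegmentationScore(dice=value, area_truth=a, area_pred=b, area_intersection=inter)


def gradient_snake_segment(
    roi_gray: np.ndarray,
    estimate: DiscEstimate,
    cfg: SnakeConfig = SnakeConfig(),
    *,
    smoothing_sigma: float = 5.0,
) -> np.ndarray:
    """Classic gradient-force snake baseline.

    Potential = negated, normalized gradient magnitude of the smoothed
    intensity; the initial contour is a circle at the *full* estimated
    radius, since gradient snakes must start near the true boundary. No
    texture-noise suppression is applied.
    """
    sm = ndi.gaussian_filter(np.asarray(roi_gray, dtype=np.float64), smoothing_sigma)
    gmag = np.hypot(*np.gradient(sm))
    pot = texture_potential(gmag, provenance={"force": "intensity-gradient"})
    contour = init_circle(estimate, cfg.n_points, radius_factor=1.0)
    final, _ = evolve(contour, pot, cfg)
    return contour_to_mask(final, roi_gray.shape)


def fcm_texture_segment(
    red_roi: np.ndarray,
    estimate: DiscEstimate,
    fcm_cfg: FcmConfig = FcmConfig(),
    *,
    margin: float = 50.0,
    closing_radius: int = 5,
) -> np.ndarray:
    """Texture-clustering + ellipse-fit baseline.

    Pixels of the enlarged analysis region are clustered on 2 features
    (Schmid #1, MR #5 of the red channel); the smaller cluster — the
    boundary-texture one, since flat retina dominates the region — is
    closed morphologically, its largest connected component's boundary is
    fitted with a direct least-squares ellipse, and the filled ellipse is
    returned.
    """
    region = enlarged_analysis_region(estimate, red_roi.shape, margin)
    sel = region.mask()
    mr8 = mr8_responses(red_roi)
    schmid1 = filter_bank_responses(red_roi, [schmid_kernel(2, 1).kernel])[0]
    feats = np.stack([schmid1, mr8[5]], axis=-1)
    zs = np.zeros_like(feats)
    for i in range(feats.shape[-1]):
        vals = feats[..., i][sel]
        sd = vals.std()
        zs[..., i] = (feats[..., i] - vals.mean()) / sd if sd > 1e-15 else 0.0
    result = fcm(zs[sel], fcm_cfg)
    labels = np.zeros(red_roi.shape, dtype=np.int64)
    labels[sel] = result.labels + 1  # 0 = outside region

    # the minority cluster carries the boundary texture
    counts = np.bincount(labels.ravel(), minlength=3)[1:]
    disc_label = int(np.argmin(counts)) + 1
    cluster = labels == disc_label
    # small opening first: isolated speckle would otherwise be bridged into
    # the boundary annulus by the closing
    cluster = binary_opening(cluster, disk(2))
    cluster = binary_closing(cluster, disk(closing_radius))
    comp = label(cluster, connectivity=2)
    if comp.max() == 0:
        raise ValueError("no disc-like component found by texture clustering")
    areas = np.bincount(comp.ravel())[1:]
    component = comp == (int(np.argmax(areas)) + 1)

    # the component is an annulus straddling the disc boundary; its radial
    # midline (per-angle mean radius) is an unbiased boundary estimate,
    # whereas raw boundary pixels over-weight the longer outer contour
    comp_pts = np.argwhere(component).astype(np.float64)
    r0f, c0f = float(estimate.center[0]), float(estimate.center[1])
    ang = np.arctan2(comp_pts[:, 0] - r0f, comp_pts[:, 1] - c0f)
    rad = np.hypot(comp_pts[:, 0] - r0f, comp_pts[:, 1] - c0f)
    bins = np.floor((ang + np.pi) / (2 * np.pi) * 120).astype(int).clip(0, 119)
    pts = []
    for b in range(120):
        hit = bins == b
        if hit.any():
            theta = (b + 0.5) / 120 * 2 * np.pi - np.pi
            r_mid = rad[hit].mean()
            pts.append((r0f + r_mid * np.sin(theta), c0f + r_mid * np.cos(theta)))
    pts = np.asarray(pts)
    if len(pts) < 5:
        raise ValueError("degenerate component boundary: fewer than 5 points")
    model = EllipseModel.from_estimate(pts[:, ::-1])  # EllipseModel expects (x, y)
    if not model:
        raise ValueError("ellipse fit failed on the component boundary")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    rows, cols = np.mgrid[0 : red_roi.shape[0], 0 : red_roi.shape[1]].astype(np.float64)
    dx, dy = cols - xc, rows - yc
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / max(a, 1e-9)
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / max(b, 1e-9)
    return u**2 + v**2 <= 1.0


def evaluate_batch(samples, methods: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every method on every (image, truth-mask) sample.

    ``methods`` maps a name to a callable(sample) -> predicted mask in
    full-image coordinates. Returns the long-format per-sample table
    (method, sample, dice) and the summary (method, mu, delta, n) with the
    mean and standard deviation of dice.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    records = []
    for idx, (image, truth) in enumerate(samples):
        for name, fn in methods.items():
            pred = fn(image)
            records.append(
                {"method": name, "sample": idx, "dice": dice(truth, pred).dice}
            )
    long = pd.DataFrame.from_records(records)
    summary = (
        long.groupby("method", sort=False)["dice"]
        .agg(mu="mean", delta=lambda s: float(np.std(s, ddof=0)), n="count")
        .reset_index()
    )
    return long, summary
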