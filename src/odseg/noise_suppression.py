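"""Texture-noise suppression before the active contour.

The cup boundary and residual vessel edges produce texture ridges inside
the disc that would trap an inflating contour early. Within an enlarged
disc-centered analysis region, pixels are soft-clustered in a 3-feature
texture space (Schmid #1, MR #5, MR #7 of the red channel) by fuzzy
c-means; the larger cluster is taken as background, cleaned by a
morphological opening, and its complement's largest connected component
becomes the estimated edge region. The texture potential is then diffusion-
inpainted over the background region so only the boundary ridge survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import disk, opening as binary_opening

from .localization import DiscEstimate
from .texture_banks import Mr8Responses, mr8_responses, schmid_kernel, filter_bank_responses
from .vessel_removal import InpaintConfig, inpaint_diffusion

log = logging.getLogger(__name__)

__all__ = [
    "FcmConfig",
    "FcmResult",
    "EdgeRegionMask",
    "AnalysisRegion",
    "NoiseSuppressionError",
    "enlarged_analysis_region",
    "build_feature_stack",
    "fcm",
    "edge_region_mask",
    "suppress_noise",
]


class NoiseSuppressionError(RuntimeError):
    """Raised when no usable edge region emerges from clustering."""


@dataclass(frozen=True)
class FcmConfig:
    n_clusters: int = 2
    fuzzifier_m: float = 2.0
    tolerance: float = 1e-5
    max_iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.fuzzifier_m <= 1.0:
            raise ValueError("fuzzifier_m must be > 1")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


@dataclass
class FcmResult:
    centers: np.ndarray  # (k, d)
    memberships: np.ndarray  # (n, k), rows sum to 1
    labels: np.ndarray  # (n,) hard argmax
    objective_trace: np.ndarray  # per-iteration objective values


@dataclass
class AnalysisRegion:
    """Disc-centered circular analysis region in ROI coordinates."""

    center: tuple[float, float]
    radius: float
    shape: tuple[int, int]

    def mask(self) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]].astype(np.float64)
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass
class EdgeRegionMask:
    edge_mask: np.ndarray
    background_mask: np.ndarray
    analysis_radius: float


def enlarged_analysis_region(
    estimate: DiscEstimate, shape: tuple[int, int], margin: float = 50.0
) -> AnalysisRegion:
    """Circular region of radius (estimated radius + margin) around the disc.

    Pixels outside it are excluded from clustering. If the circle exceeds
    the ROI it is kept (the mask is implicitly clipped) with a warning.
    """
    estimate.validate()
    r0, c0 = estimate.center
    radius = estimate.radius + margin
    if (
        r0 - radius < 0
        or c0 - radius < 0
        or r0 + radius > shape[0] - 1
        or c0 + radius > shape[1] - 1
    ):
        log.warning("analysis region of radius %.0f exceeds the ROI; clipped", radius)
    return AnalysisRegion(center=(float(r0), float(c0)), radius=float(radius), shape=shape)


def build_feature_stack(
    red_roi: np.ndarray,
    region: AnalysisRegion | None = None,
    *,
    mr8: Mr8Responses | None = None,
    schmid_first: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel 3-vector [Schmid #1, MR #5, MR #7] of the red channel.

    Each feature is z-scored over the analysis region (whole image if no
    region is given); a feature that is constant there maps to zeros.
    Precomputed responses can be passed to avoid refiltering.
    """
    if mr8 is None:
        mr8 = mr8_responses(red_roi)
    if schmid_first is None:
        schmid_first = filter_bank_responses(red_roi, [schmid_kernel(2, 1).kernel])[0]
    feats = np.stack([schmid_first, mr8[5], mr8[7]], axis=-1)
    sel = region.mask() if region is not None else np.ones(red_roi.shape, dtype=bool)
    out = np.zeros_like(feats)
    for i in range(feats.shape[-1]):
        vals = feats[..., i][sel]
        mu, sd = float(vals.mean()), float(vals.std())
        out[..., i] = (feats[..., i] - mu) / sd if sd > 1e-15 else 0.0
    return out


def fcm(points: np.ndarray, cfg: FcmConfig = FcmConfig()) -> FcmResult:
    """Fuzzy c-means with seeded random membership initialization.

    Alternates membership and center updates of the standard algorithm
    (memberships u_ik proportional to (1/d_ik^2)^(1/(m-1)), centers the
    u^m-weighted means) until the objective changes by less than
    ``tolerance`` or ``max_iterations`` is reached.
    """
    cfg.validate()
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be (n, d)")
    if np.unique(points, axis=0).shape[0] < cfg.n_clusters:
        raise ValueError("need at least n_clusters distinct points")
    n, _ = points.shape
    rng = np.random.default_rng(cfg.seed)
    u = rng.random((n, cfg.n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    exponent = 2.0 / (cfg.fuzzifier_m - 1.0)
    objective_trace = []
    prev_obj = np.inf
    for _ in range(cfg.max_iterations):
        um = u**cfg.fuzzifier_m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        obj = float((um * d2).sum())
        objective_trace.append(obj)
        d2s = np.maximum(d2, 1e-300)
        inv = d2s ** (-exponent / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        zero_hits = d2 <= 1e-300
        rows = zero_hits.any(axis=1)
        if rows.any():
            u[rows] = zero_hits[rows] / zero_hits[rows].sum(axis=1, keepdims=True)
        if abs(prev_obj - obj) < cfg.tolerance:
            break
        prev_obj = obj
    labels = np.argmax(u, axis=1)
    return FcmResult(
        centers=centers,
        memberships=u,
        labels=labels,
        objective_trace=np.asarray(objective_trace),
    )


def edge_region_mask(
    labels: np.ndarray,
    region: AnalysisRegion,
    open_se_radius: int = 5,
) -> EdgeRegionMask:
    """Split the clustered analysis region into edge and background masks.

    The larger-area cluster is the background (the boundary ring is the
    minority class); a binary opening with a disc element absorbs speckle
    holes, the complement within the analysis disc is taken, and its
    largest 8-connected component becomes the edge region.
    """
    sel = region.mask()
    labels = np.asarray(labels)
    if labels.shape != sel.shape:
        raise ValueError("labels raster must match the region shape")
    cluster1 = (labels.astype(bool)) & sel
    cluster0 = (~labels.astype(bool)) & sel
    background = cluster0 if cluster0.sum() >= cluster1.sum() else cluster1
    opened = binary_opening(background, disk(open_se_radius))
    candidates = sel & ~opened
    comp = label(candidates, connectivity=2)
    if comp.max() == 0:
        raise NoiseSuppressionError("no edge region left after opening")
    areas = np.bincount(comp.ravel())[1:]
    edge = comp == (int(np.argmax(areas)) + 1)
    if not edge.any():
        raise NoiseSuppressionError("empty edge region")
    return EdgeRegionMask(
        edge_mask=edge,
        background_mask=sel & ~edge,
        analysis_radius=region.radius,
    )


def suppress_noise(
    texture: np.ndarray,
    edge_region: EdgeRegionMask,
    cfg: InpaintConfig | None = None,
) -> np.ndarray:
    """Inpaint the texture potential over the background region.

    Diffusion inpainting (Dirichlet data from the edge region and the
    analysis-circle boundary) removes cup-boundary and vessel-edge ridges
    while keeping the potential smooth — assigning a constant would create
    spurious extrema that stop the contour. Edge-region pixels are
    untouched bit-exactly.
    """
    cfg = cfg or InpaintConfig(mask_dilation=0)
    if cfg.mask_dilation != 0:
        cfg = InpaintConfig(
            mask_dilation=0, tolerance=cfg.tolerance, max_iterations=cfg.max_iterations
        )
    return inpaint_diffusion(texture, edge_region.background_mask, cfg)
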