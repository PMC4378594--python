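"""End-to-end optic-disc segmentation pipeline.

Stage order: HSI intensity -> template match -> Canny + circle Hough ->
900x900 ROI -> vessel inpainting -> texture banks (MR8 edge response) ->
CLAHE -> fuzzy-c-means noise suppression -> texture potential -> balloon
snake -> disc mask in full-image coordinates. Every stage artifact is kept
on the result object; the whole run is deterministic for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field

import numpy as np

from . import balloon_snake as bs
from . import localization as loc
from . import noise_suppression as ns
from . import texture_banks as tb
from . import vessel_removal as vr

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "segment_image"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one (TOML-loadable) place."""

    roi_side: int = 900
    template: loc.TemplateSpec = field(default_factory=loc.TemplateSpec)
    match_downscale: int = 4
    refine_window: int = 64
    canny_threshold: float = 0.4
    canny_sigma: float = 5.0
    hough_radii: tuple[int, ...] = loc.DEFAULT_HOUGH_RADII
    inpaint: vr.InpaintConfig = field(default_factory=vr.InpaintConfig)
    potential_response: int = 3  # 1-based MR8 index driving the snake
    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    analysis_margin: float = 50.0
    fcm: ns.FcmConfig = field(default_factory=ns.FcmConfig)
    open_se_radius: int = 5
    snake: bs.SnakeConfig = field(default_factory=bs.SnakeConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {}
        nested = {
            "template": loc.TemplateSpec,
            "inpaint": vr.InpaintConfig,
            "fcm": ns.FcmConfig,
            "snake": bs.SnakeConfig,
        }
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            elif key in ("hough_radii", "clahe_tiles"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    estimate: loc.DiscEstimate
    match_center: tuple[int, int]
    roi: loc.RoiWindow
    roi_devesseled: np.ndarray
    vessel_removal_skipped: bool
    texture: np.ndarray
    texture_enhanced: np.ndarray
    edge_region: ns.EdgeRegionMask | None
    noise_suppression_skipped: bool
    potential: bs.TexturePotential
    contour: bs.Contour
    trace: bs.EvolveTrace
    disc_mask_roi: np.ndarray
    disc_mask: np.ndarray  # full-image coordinates
    timings: dict = field(default_factory=dict)
    config: PipelineConfig = field(default_factory=PipelineConfig)


def segment_image(
    rgb: np.ndarray,
    vessel_mask: np.ndarray | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Segment the optic disc of one RGB fundus image.

    ``vessel_mask`` is the binary vessel segmentation aligned with the
    image; without one, vessel removal is skipped with a warning. The image
    must be at least 1000x1000 px so the 900x900 ROI is meaningful.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if min(rgb.shape[:2]) < 1000:
        raise ValueError("image must be at least 1000x1000 px to contain the ROI")
    timings: dict[str, float] = {}

    def _tic(stage: str, t0: float) -> None:
        timings[stage] = time.perf_counter() - t0
        log.info("stage %-18s %6.2f s", stage, timings[stage])

    t0 = time.perf_counter()
    estimate, match_center = loc.locate_disc(
        rgb,
        config.template,
        downscale=config.match_downscale,
        refine_window=config.refine_window,
        roi_side=config.roi_side,
        canny_threshold=config.canny_threshold,
        canny_sigma=config.canny_sigma,
        radii=config.hough_radii,
    )
    _tic("localization", t0)

    roi = loc.extract_roi(rgb, estimate.center, side=config.roi_side)
    est_roi = loc.DiscEstimate(
        center=(config.roi_side // 2, config.roi_side // 2),
        radius=estimate.radius,
        score=estimate.score,
    )

    t0 = time.perf_counter()
    skipped_vessels = vessel_mask is None
    if skipped_vessels:
        log.warning("no vessel mask supplied; vessel removal skipped")
        roi_clean = roi.image.copy()
    else:
        vmask_roi = loc.extract_roi(
            np.asarray(vessel_mask, dtype=bool), estimate.center, side=config.roi_side
        ).image
        roi_clean = vr.inpaint_diffusion(roi.image, vmask_roi, config.inpaint)
    _tic("vessel_removal", t0)

    t0 = time.perf_counter()
    red = roi_clean[..., 0]
    mr8 = tb.mr8_responses(red)
    schmid1 = tb.filter_bank_responses(red, [tb.schmid_kernel(2, 1).kernel])[0]
    texture = mr8[config.potential_response]
    enhanced = tb.clahe_enhance(texture, config.clahe_clip_limit, config.clahe_tiles)
    _tic("texture", t0)

    t0 = time.perf_counter()
    region = ns.enlarged_analysis_region(est_roi, red.shape, config.analysis_margin)
    edge_region: ns.EdgeRegionMask | None = None
    suppression_skipped = False
    try:
        feats = ns.build_feature_stack(red, region, mr8=mr8, schmid_first=schmid1)
        sel = region.mask()
        result = ns.fcm(feats[sel], config.fcm)
        labels = np.zeros(red.shape, dtype=np.int64)
        labels[sel] = result.labels
        edge_region = ns.edge_region_mask(labels, region, config.open_se_radius)
        clean = ns.suppress_noise(enhanced, edge_region, config.inpaint)
    except ns.NoiseSuppressionError as exc:
        log.warning("noise suppression failed (%s); using unsuppressed texture", exc)
        suppression_skipped = True
        clean = enhanced
    _tic("noise_suppression", t0)

    t0 = time.perf_counter()
    pot = bs.texture_potential(
        clean,
        provenance={
            "response": f"MR8 #{config.potential_response}",
            "clahe": True,
            "noise_suppressed": not suppression_skipped,
        },
    )
    contour0 = bs.init_circle(est_roi, config.snake.n_points)
    contour, trace = bs.evolve(contour0, pot, config.snake)
    disc_mask_roi = bs.contour_to_mask(contour, red.shape)
    disc_mask = roi.mask_to_full(disc_mask_roi, rgb.shape[:2])
    _tic("snake", t0)

    return PipelineResult(
        estimate=estimate,
        match_center=match_center,
        roi=roi,
        roi_devesseled=roi_clean,
        vessel_removal_skipped=skipped_vessels,
        texture=texture,
        texture_enhanced=enhanced,
        edge_region=edge_region,
        noise_suppression_skipped=suppression_skipped,
        potential=pot,
        contour=contour,
        trace=trace,
        disc_mask_roi=disc_mask_roi,
        disc_mask=disc_mask,
        timings=timings,
        config=config,
    )
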