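"""Shared fixtures: one seeded synthetic benchmark batch reused suite-wide.

The heavy end-to-end runs (20 PPA fixtures through the full pipeline and
both baselines) happen once per session; individual tests assert different
properties of the cached records. Per-record artifacts that no test needs
are dropped to keep memory bounded.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage as ndi

sys.path.insert(0, str(Path(__file__).parent))

from odseg import extract_roi, generate_fundus, locate_disc, random_spec, remove_vessels_mean
from odseg.benchmark import run_single
from odseg.fixtures import SyntheticFundusSample
from odseg.localization import DiscEstimate

N_BENCH = 20  # PPA benchmark seeds
N_VESSEL_MAD = 10  # seeds with the vessel-residual comparison
N_KEEP_POTENTIAL = 3  # seeds keeping the texture potential for re-runs


@dataclass
class SlimRecord:
    seed: int
    dice_proposed: float
    dice_gradient_snake: float
    dice_fcm_ellipse: float
    match_error_px: float
    center_error_px: float
    radius_error_px: float
    ppa_crossing_px: float
    suppression_skipped: bool
    cup_ring_overlap: float | None
    vessel_mad_inpaint: float | None
    vessel_mad_mean: float | None
    potential: object | None
    est_roi: DiscEstimate | None
    roi_shape: tuple[int, int] | None


def _cup_ring_overlap(rec) -> float | None:
    if rec.result.edge_region is None:
        return None
    cup_roi = extract_roi(
        rec.sample.cup_mask, rec.result.estimate.center, rec.result.config.roi_side
    ).image
    outline = cup_roi & ~ndi.binary_erosion(cup_roi)
    ring = ndi.binary_dilation(outline, iterations=4)
    if ring.sum() == 0:
        return None
    return float((ring & rec.result.edge_region.edge_mask).sum() / ring.sum())


def _vessel_mads(rec) -> tuple[float, float]:
    spec = rec.sample.spec
    clean = generate_fundus(dataclasses.replace(spec, n_vessels=0))
    center = rec.result.estimate.center
    side = rec.result.config.roi_side
    ref_red = extract_roi(clean.rgb_image, center, side).image[..., 0]
    vmask = extract_roi(rec.sample.vessel_mask, center, side).image
    inpainted_red = rec.result.roi_devesseled[..., 0]
    mean_red = remove_vessels_mean(rec.result.roi.image[..., 0], vmask, 31)
    mad_inpaint = float(np.abs(inpainted_red - ref_red)[vmask].mean())
    mad_mean = float(np.abs(mean_red - ref_red)[vmask].mean())
    return mad_inpaint, mad_mean


@pytest.fixture(scope="session")
def bench_batch() -> list[SlimRecord]:
    """20 seeded PPA fixtures through the pipeline and both baselines."""
    slims = []
    for i in range(N_BENCH):
        rec = run_single(1000 + i, ppa=True)
        spec = rec.sample.spec
        mad_i = mad_m = None
        if i < N_VESSEL_MAD:
            mad_i, mad_m = _vessel_mads(rec)
        slims.append(
            SlimRecord(
                seed=rec.seed,
                dice_proposed=rec.dice_proposed,
                dice_gradient_snake=rec.dice_gradient_snake,
                dice_fcm_ellipse=rec.dice_fcm_ellipse,
                match_error_px=float(
                    np.hypot(
                        rec.result.match_center[0] - spec.disc_center[0],
                        rec.result.match_center[1] - spec.disc_center[1],
                    )
                ),
                center_error_px=rec.center_error_px,
                radius_error_px=rec.radius_error_px,
                ppa_crossing_px=rec.ppa_crossing_px,
                suppression_skipped=rec.result.noise_suppression_skipped,
                cup_ring_overlap=_cup_ring_overlap(rec),
                vessel_mad_inpaint=mad_i,
                vessel_mad_mean=mad_m,
                potential=rec.result.potential if i < N_KEEP_POTENTIAL else None,
                est_roi=DiscEstimate(
                    center=(rec.result.config.roi_side // 2, rec.result.config.roi_side // 2),
                    radius=rec.result.estimate.radius,
                    score=rec.result.estimate.score,
                )
                if i < N_KEEP_POTENTIAL
                else None,
                roi_shape=rec.result.disc_mask_roi.shape if i < N_KEEP_POTENTIAL else None,
            )
        )
        del rec
    return slims


@pytest.fixture(scope="session")
def loc_batch() -> list[dict]:
    """Localization errors over 20 no-PPA fixtures (no full pipeline)."""
    out = []
    for i in range(20):
        spec = random_spec(500 + i, ppa=False)
        sample = generate_fundus(spec)
        est, match = locate_disc(sample.rgb_image)
        out.append(
            {
                "match_error": float(
                    np.hypot(match[0] - spec.disc_center[0], match[1] - spec.disc_center[1])
                ),
                "center_error": float(
                    np.hypot(
                        est.center[0] - spec.disc_center[0],
                        est.center[1] - spec.disc_center[1],
                    )
                ),
                "radius_error": float(abs(est.radius - 0.5 * sum(spec.disc_semi_axes))),
            }
        )
        del sample
    return out


@pytest.fixture(scope="session")
def ppa_sample() -> SyntheticFundusSample:
    """One PPA fixture for determinism / fallback pipeline tests."""
    return generate_fundus(random_spec(2024, ppa=True))


@pytest.fixture(scope="session")
def clean_roi():
    """Vessel-free, PPA-free fixture cropped to the ROI at the true center.

    Returns (red_roi, gray_roi, true_estimate_in_roi, spec) for baseline
    tests that need known clean geometry.
    """
    spec = dataclasses.replace(random_spec(888, ppa=False), n_vessels=0)
    sample = generate_fundus(spec)
    center = (int(round(spec.disc_center[0])), int(round(spec.disc_center[1])))
    roi = extract_roi(sample.rgb_image, center, 900)
    est = DiscEstimate(center=(450, 450), radius=0.5 * sum(spec.disc_semi_axes), score=1.0)
    gray = roi.image.mean(axis=-1)
    return roi.image[..., 0], gray, est, spec
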