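"""Seeded synthetic fundus-like images with ground truth.

Real evaluation data for optic-disc segmentation (fundus photographs with
expert disc masks) is rarely redistributable, so this module renders
fundus-like scenes with known geometry: a bright, vertically slightly oval
disc of 260-380 px width on a large retina-colored background with smooth
illumination inhomogeneity, a brighter cup inside the disc, dark branching
vessels emerging from the disc center, and an optional crescent of
peripapillary atrophy (PPA) of intermediate brightness abutting the disc.
Every sample carries binary ground-truth masks for disc, cup, vessels and
PPA, and is bit-reproducible from its spec (including the seed).

Intensities are float in [0, 1]; images are written to disk as 8-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.special import erf
from skimage.draw import disk as draw_disk

__all__ = [
    "SyntheticFundusSpec",
    "SyntheticFundusSample",
    "generate_fundus",
    "generate_vessel_tree",
    "random_spec",
]

# Per-channel colors (R, G, B) of the scene elements, chosen so the red
# channel carries the strongest disc/background contrast, as it does in
# fundus photographs.
_BACKGROUND_RGB = (0.50, 0.33, 0.13)
_DISC_RGB = (0.97, 0.75, 0.42)
_CUP_EXTRA = (0.04, 0.07, 0.10)  # cup is brighter than the disc rim
_PPA_RGB = (0.70, 0.48, 0.24)  # between background and disc in every channel
_VESSEL_FACTOR = 0.45  # multiplicative darkening under the vessel mask


@dataclass(frozen=True)
class SyntheticFundusSpec:
    """Parameters of one synthetic fundus scene.

    Defaults satisfy the geometry every downstream stage assumes: disc
    width (2x horizontal semi-axis) in [260, 380] px, vertical semi-axis
    >= horizontal (vertically slightly oval), cup strictly inside the disc,
    PPA disjoint from the disc.
    """

    image_height: int = 1100
    image_width: int = 1100
    disc_center: tuple[float, float] = (550.0, 550.0)  # (row, col)
    disc_semi_axes: tuple[float, float] = (172.0, 160.0)  # (vertical, horizontal)
    disc_brightness: float = 1.0  # scales disc/background contrast
    cup_ratio: float = 0.45  # cup semi-axes as a fraction of the disc's
    n_vessels: int = 5
    vessel_width_range: tuple[float, float] = (6.0, 12.0)
    ppa_enabled: bool = False
    ppa_thickness: float = 40.0  # radial extent of the crescent, px
    ppa_brightness: float = 1.0  # scales PPA contrast above background
    illumination_tilt: float = 6e-5  # intensity per px along the tilt axis
    noise_sigma: float = 0.012
    edge_softness: float = 5.0  # erf transition half-width of disc/cup/PPA edges
    seed: int = 0

    def validate(self) -> None:
        a_v, a_h = self.disc_semi_axes
        width = 2.0 * a_h
        if not (260.0 <= width <= 380.0):
            raise ValueError(
                f"disc width {width:.1f} px outside the modeled range [260, 380]"
            )
        if a_v < a_h:
            raise ValueError("vertical semi-axis must be >= horizontal (oval disc)")
        if not (0.0 < self.cup_ratio < 1.0):
            raise ValueError("cup_ratio must lie strictly inside (0, 1)")
        r, c = self.disc_center
        margin = 500.0
        for name, dist in (
            ("top", r),
            ("left", c),
            ("bottom", self.image_height - 1 - r),
            ("right", self.image_width - 1 - c),
        ):
            if dist < margin:
                raise ValueError(
                    f"disc center is {dist:.0f} px from the {name} border; "
                    f"at least {margin:.0f} px are required so the disc, its "
                    "PPA crescent and the analysis ROI fit inside the image"
                )
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        lo, hi = self.vessel_width_range
        if not (0 < lo <= hi):
            raise ValueError("vessel_width_range must be 0 < lo <= hi")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticFundusSpec":
        raw = json.loads(text)
        for key in ("disc_center", "disc_semi_axes", "vessel_width_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticFundusSample:
    rgb_image: np.ndarray  # (H, W, 3) float in [0, 1]
    disc_mask: np.ndarray  # (H, W) bool
    cup_mask: np.ndarray
    vessel_mask: np.ndarray
    ppa_mask: np.ndarray
    spec: SyntheticFundusSpec = field(repr=False)


def _rng(spec: SyntheticFundusSpec, stream: int) -> np.random.Generator:
    # Independent child streams so e.g. the vessel RNG does not perturb the
    # background when n_vessels changes.
    return np.random.default_rng([spec.seed, stream])


def _elliptic_radius(spec: SyntheticFundusSpec, scale: float = 1.0) -> np.ndarray:
    """Normalized elliptic radius rho (rho == 1 on the ellipse boundary)."""
    rr, cc = np.mgrid[0 : spec.image_height, 0 : spec.image_width].astype(np.float64)
    r0, c0 = spec.disc_center
    a_v, a_h = spec.disc_semi_axes
    return np.sqrt(((rr - r0) / (a_v * scale)) ** 2 + ((cc - c0) / (a_h * scale)) ** 2)


def _soft_inside(rho: np.ndarray, mean_axis: float, softness: float) -> np.ndarray:
    """Smooth indicator of rho <= 1 with an erf edge of ~softness px."""
    signed_dist = (rho - 1.0) * mean_axis  # approx. px distance to the boundary
    return 0.5 * (1.0 - erf(signed_dist / (softness * np.sqrt(2.0))))


def _background(spec: SyntheticFundusSpec) -> np.ndarray:
    """Smooth illumination field multiplying the base colors (mean ~1)."""
    rng = _rng(spec, 0)
    rr, cc = np.mgrid[0 : spec.image_height, 0 : spec.image_width].astype(np.float64)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.cos(theta) * (rr - spec.image_height / 2) + np.sin(theta) * (
        cc - spec.image_width / 2
    )
    tilt = spec.illumination_tilt * axis
    # low-frequency smooth field: heavily blurred white noise on a coarse grid
    coarse = rng.standard_normal((spec.image_height // 64 + 2, spec.image_width // 64 + 2))
    smooth = ndi.zoom(coarse, 64, order=3)[: spec.image_height, : spec.image_width]
    smooth = ndi.gaussian_filter(smooth, 32)
    smooth *= 0.05 / max(np.abs(smooth).max(), 1e-12)
    return 1.0 + tilt + smooth


def generate_vessel_tree(
    spec: SyntheticFundusSpec, return_centerlines: bool = False
) -> np.ndarray:
    """Binary mask of branching vessels emanating from the disc center.

    Vessels are random-walk centerlines stamped with disks of half the
    sampled vessel width; each main vessel starts inside the disc (so the
    tree is 8-connected to the disc interior) and may spawn one branch.
    With ``return_centerlines`` the (n, 2) array of stamped centerline
    points is returned alongside the mask.
    """
    spec.validate()
    mask = np.zeros((spec.image_height, spec.image_width), dtype=bool)
    centerlines: list[np.ndarray] = []
    if spec.n_vessels == 0:
        return (mask, np.zeros((0, 2))) if return_centerlines else mask
    rng = _rng(spec, 1)
    r0, c0 = spec.disc_center
    a_v, a_h = spec.disc_semi_axes
    mean_axis = 0.5 * (a_v + a_h)
    shape = mask.shape

    def _walk(start: np.ndarray, direction: float, width: float, n_steps: int) -> list:
        pos = start.copy()
        ang = direction
        pts = []
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.06)
            pos = pos + 3.0 * np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]):
                break
            pts.append((pos.copy(), ang))
            centerlines.append(pos.copy())
            rr, cc = draw_disk((pos[0], pos[1]), max(width / 2.0, 1.0), shape=shape)
            mask[rr, cc] = True
        return pts

    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=spec.n_vessels))
    for ang0 in angles:
        width = rng.uniform(*spec.vessel_width_range)
        start = np.array(
            [r0 + 0.25 * mean_axis * np.sin(ang0), c0 + 0.25 * mean_axis * np.cos(ang0)]
        )
        n_steps = int(rng.integers(150, 280))
        pts = _walk(start, ang0, width, n_steps)
        if pts and rng.random() < 0.8:
            # one branch from a point along the parent, slightly thinner
            base_pos, base_ang = pts[int(rng.integers(len(pts) // 4, len(pts)))]
            side = 1.0 if rng.random() < 0.5 else -1.0
            _walk(
                base_pos,
                base_ang + side * rng.uniform(0.4, 0.9),
                max(width * 0.7, spec.vessel_width_range[0] * 0.7),
                int(rng.integers(80, 160)),
            )
    if return_centerlines:
        return mask, np.asarray(centerlines)
    return mask


def generate_fundus(spec: SyntheticFundusSpec) -> SyntheticFundusSample:
    """Render one synthetic fundus scene with ground-truth masks."""
    spec.validate()
    a_v, a_h = spec.disc_semi_axes
    mean_axis = 0.5 * (a_v + a_h)

    rho_disc = _elliptic_radius(spec)
    rho_cup = _elliptic_radius(spec, scale=spec.cup_ratio)
    disc_mask = rho_disc <= 1.0
    cup_mask = rho_cup <= 1.0

    w_disc = _soft_inside(rho_disc, mean_axis, spec.edge_softness)
    w_cup = _soft_inside(rho_cup, mean_axis * spec.cup_ratio, spec.edge_softness)

    # PPA: partial annulus (crescent) on the temporal side of the disc
    ppa_mask = np.zeros_like(disc_mask)
    w_ppa = np.zeros_like(rho_disc)
    if spec.ppa_enabled:
        rr, cc = np.mgrid[0 : spec.image_height, 0 : spec.image_width].astype(np.float64)
        theta = np.arctan2(rr - spec.disc_center[0], cc - spec.disc_center[1])
        rho_out = 1.0 + spec.ppa_thickness / mean_axis
        half_angle = np.deg2rad(80.0)
        ppa_mask = (rho_disc > 1.0) & (rho_disc <= rho_out) & (np.abs(theta) <= half_angle)
        # the scleral (inner) border of atrophy is crisp; the outer border
        # fades diffusely into the retina
        w_outer = _soft_inside(rho_disc / rho_out, mean_axis * rho_out, 3.0 * spec.edge_softness)
        angular = 0.5 * (1.0 - erf((np.abs(theta) - half_angle) / 0.12))
        w_ppa = np.clip(w_outer - w_disc, 0.0, 1.0) * angular

    illum = _background(spec)
    vessel_mask = generate_vessel_tree(spec)

    channels = []
    for ch in range(3):
        bg = _BACKGROUND_RGB[ch]
        disc = bg + spec.disc_brightness * (_DISC_RGB[ch] - bg)
        cup = disc + _CUP_EXTRA[ch]
        ppa = bg + spec.ppa_brightness * (_PPA_RGB[ch] - bg)
        img = np.full(rho_disc.shape, bg)
        img = img * (1.0 - w_ppa) + ppa * w_ppa
        img = img * (1.0 - w_disc) + disc * w_disc
        img = img * (1.0 - w_cup) + cup * w_cup
        img *= illum
        channels.append(img)
    rgb = np.stack(channels, axis=-1)

    noise = _rng(spec, 2).normal(0.0, spec.noise_sigma, size=rgb.shape)
    rgb = rgb + noise
    rgb = np.clip(rgb, 0.01, 1.0)
    # vessels darken whatever they cover, in every channel, strictly
    rgb[vessel_mask] *= _VESSEL_FACTOR

    return SyntheticFundusSample(
        rgb_image=rgb,
        disc_mask=disc_mask,
        cup_mask=cup_mask,
        vessel_mask=vessel_mask,
        ppa_mask=ppa_mask,
        spec=spec,
    )


def random_spec(seed: int, *, ppa: bool = False, size: tuple[int, int] = (1100, 1100)) -> SyntheticFundusSpec:
    """Draw a randomized but valid spec for batch experiments.

    Disc width is sampled across its full modeled range [260, 380] px, the
    vertical elongation in [2%, 12%], and the center jittered while keeping
    the required border margin.
    """
    rng = np.random.default_rng([seed, 99])
    h, w = size
    a_h = rng.uniform(132.0, 188.0)
    a_v = a_h * rng.uniform(1.02, 1.07)
    max_jit_r = max((h - 1) / 2.0 - 500.0, 0.0)
    max_jit_c = max((w - 1) / 2.0 - 500.0, 0.0)
    center = (
        (h - 1) / 2.0 + rng.uniform(-max_jit_r, max_jit_r),
        (w - 1) / 2.0 + rng.uniform(-max_jit_c, max_jit_c),
    )
    return SyntheticFundusSpec(
        image_height=h,
        image_width=w,
        disc_center=center,
        disc_semi_axes=(a_v, a_h),
        cup_ratio=rng.uniform(0.35, 0.55),
        n_vessels=int(rng.integers(4, 7)),
        ppa_enabled=ppa,
        ppa_thickness=rng.uniform(30.0, 55.0),
        noise_sigma=0.012,
        seed=seed,
    )
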