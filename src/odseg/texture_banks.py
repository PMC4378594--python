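"""Rotation-invariant texture filter banks and texture enhancement.

Two banks are provided:

* the Schmid bank — 12 isotropic "Gabor-like" kernels, a radial cosine of
  tau cycles modulated by a Gaussian envelope of scale sigma:
  F(x, y) = F0 + cos(sqrt(x^2+y^2) * pi * tau / sigma) * exp(-(x^2+y^2)/(2 sigma^2)),
  with F0 chosen so each kernel sums to zero, then L1-normalized;
* the Root Filter Set (RFS) — 38 kernels: first- and second-derivative-of-
  Gaussian filters at 6 orientations x 3 scales (36), plus an isotropic
  Gaussian and a Laplacian of Gaussian. Collapsing each oriented family x
  scale to its maximum response magnitude over orientations yields the 8
  rotation-invariant MR8 responses.

CLAHE is applied to a selected response to strengthen weak boundary texture
before it drives the active contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2
from skimage.exposure import equalize_adapthist

__all__ = [
    "SchmidKernel",
    "RfsKernel",
    "RfsBank",
    "Mr8Responses",
    "SCHMID_PAIRS",
    "schmid_kernel",
    "schmid_bank",
    "schmid_responses",
    "rfs_bank",
    "rfs_responses",
    "mr8_responses",
    "clahe_enhance",
    "filter_bank_responses",
]

#: The 12 (sigma, tau) pairs of the Schmid bank, in canonical order.
SCHMID_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 1), (4, 1), (4, 2), (6, 1), (6, 2), (6, 3),
    (8, 1), (8, 2), (8, 3), (10, 1), (10, 2), (10, 3),
)

#: MR8 response ordering: edge (odd) family over the 3 scales, then bar
#: (even) family, then the isotropic Gaussian and Laplacian of Gaussian.
MR8_ORDER: tuple[str, ...] = (
    "edge1", "edge2", "edge3", "bar1", "bar2", "bar3", "gaussian", "log",
)

_RFS_SCALES: tuple[tuple[float, float], ...] = ((3.0, 1.0), (6.0, 2.0), (12.0, 4.0))
_RFS_ORIENTATIONS: tuple[float, ...] = tuple(np.deg2rad(a) for a in range(0, 180, 30))
_RFS_SUPPORT = 49
_RFS_ISO_SIGMA = 10.0


@dataclass(frozen=True)
class SchmidKernel:
    sigma: float
    tau: int
    kernel: np.ndarray
    f0: float


@dataclass(frozen=True)
class RfsKernel:
    family: str  # "edge" | "bar" | "gaussian" | "log"
    scale_index: int  # 1-based; 0 for the isotropic pair
    orientation: float  # radians; nan for the isotropic pair
    kernel: np.ndarray


@dataclass(frozen=True)
class RfsBank:
    kernels: tuple[RfsKernel, ...]

    def __post_init__(self):
        if len(self.kernels) != 38:
            raise ValueError("RFS must hold exactly 38 kernels")


@dataclass(frozen=True)
class Mr8Responses:
    responses: tuple[np.ndarray, ...]
    order: tuple[str, ...] = MR8_ORDER

    def __getitem__(self, index_1based: int) -> np.ndarray:
        """1-based access matching the bank's printed numbering."""
        return self.responses[index_1based - 1]


def schmid_kernel(sigma: float, tau: int) -> SchmidKernel:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    half = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r = np.hypot(x, y)
    g = np.cos(r * np.pi * tau / sigma) * np.exp(-(r**2) / (2.0 * sigma**2))
    f0 = -g.mean()  # offset forcing zero DC response
    k = g + f0
    k /= np.abs(k).sum()
    return SchmidKernel(sigma=float(sigma), tau=int(tau), kernel=k, f0=float(f0))


def schmid_bank() -> list[SchmidKernel]:
    return [schmid_kernel(s, t) for s, t in SCHMID_PAIRS]


def filter_bank_responses(gray: np.ndarray, kernels: list[np.ndarray]) -> list[np.ndarray]:
    """Convolve one image with many kernels sharing a single image FFT.

    Boundary handling is symmetric (edge-reflecting) padding by the largest
    kernel half-width; outputs have the input's shape. True convolution
    (kernels flipped), which coincides with correlation for every symmetric
    kernel in these banks.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    half = max(k.shape[0] // 2 for k in kernels)
    padded = np.pad(gray, half, mode="symmetric")
    fh = next_fast_len(padded.shape[0] + 2 * half)
    fw = next_fast_len(padded.shape[1] + 2 * half)
    img_f = rfft2(padded, s=(fh, fw))
    out = []
    for k in kernels:
        kh = k.shape[0] // 2
        resp_f = img_f * rfft2(k, s=(fh, fw))
        full = irfft2(resp_f, s=(fh, fw))
        # align: full conv of padded image starts at index kh + pad offset
        r0 = half + kh
        c0 = half + kh
        out.append(full[r0 : r0 + gray.shape[0], c0 : c0 + gray.shape[1]].copy())
    return out


def schmid_responses(gray: np.ndarray) -> list[np.ndarray]:
    """Responses of the 12 Schmid kernels, in canonical (sigma, tau) order."""
    return filter_bank_responses(gray, [k.kernel for k in schmid_bank()])


def _oriented_gaussian_derivative(
    sigma_long: float, sigma_short: float, theta: float, order: int
) -> np.ndarray:
    """Derivative-of-Gaussian kernel elongated along ``theta``.

    The Gaussian envelope has std ``sigma_long`` along the orientation and
    ``sigma_short`` across it; the derivative (1st = edge, 2nd = bar) is
    taken across the orientation. Zero-mean enforced, then L1-normalized.
    """
    half = _RFS_SUPPORT // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    u = np.cos(theta) * x + np.sin(theta) * y  # along the orientation
    v = -np.sin(theta) * x + np.cos(theta) * y  # across it
    g = np.exp(-(u**2) / (2 * sigma_long**2) - (v**2) / (2 * sigma_short**2))
    if order == 1:
        k = -v / sigma_short**2 * g
    else:
        k = (v**2 / sigma_short**4 - 1.0 / sigma_short**2) * g
    k = k - k.mean()
    return k / np.abs(k).sum()


def _isotropic_gaussian(sigma: float) -> np.ndarray:
    half = _RFS_SUPPORT // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    g = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    return g / g.sum()


def _log_kernel(sigma: float) -> np.ndarray:
    half = _RFS_SUPPORT // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r2 = x**2 + y**2
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2 * sigma**2))
    k = k - k.mean()
    return k / np.abs(k).sum()


def rfs_bank() -> RfsBank:
    """The 38-kernel Root Filter Set with per-kernel metadata."""
    kernels: list[RfsKernel] = []
    for family, order in (("edge", 1), ("bar", 2)):
        for scale_index, (s_long, s_short) in enumerate(_RFS_SCALES, start=1):
            for theta in _RFS_ORIENTATIONS:
                kernels.append(
                    RfsKernel(
                        family=family,
                        scale_index=scale_index,
                        orientation=float(theta),
                        kernel=_oriented_gaussian_derivative(s_long, s_short, theta, order),
                    )
                )
    kernels.append(RfsKernel("gaussian", 0, float("nan"), _isotropic_gaussian(_RFS_ISO_SIGMA)))
    kernels.append(RfsKernel("log", 0, float("nan"), _log_kernel(_RFS_ISO_SIGMA)))
    return RfsBank(kernels=tuple(kernels))


def rfs_responses(gray: np.ndarray, bank: RfsBank | None = None) -> list[np.ndarray]:
    bank = bank or rfs_bank()
    return filter_bank_responses(gray, [k.kernel for k in bank.kernels])


def mr8_responses(gray: np.ndarray, bank: RfsBank | None = None) -> Mr8Responses:
    """Collapse the 38 RFS responses to the 8 rotation-invariant MR8 maps.

    For each oriented family x scale the pointwise maximum response
    *magnitude* over the 6 orientations is taken (the odd edge filters flip
    sign under a 180-degree orientation shift, so the magnitude is the
    rotation-invariant quantity); the two isotropic responses pass through.
    """
    bank = bank or rfs_bank()
    responses = rfs_responses(gray, bank)
    grouped: dict[str, list[np.ndarray]] = {}
    for meta, resp in zip(bank.kernels, responses):
        if meta.family in ("edge", "bar"):
            grouped.setdefault(f"{meta.family}{meta.scale_index}", []).append(np.abs(resp))
        else:
            grouped[meta.family] = [resp]
    out = tuple(np.max(np.stack(grouped[name]), axis=0) for name in MR8_ORDER)
    return Mr8Responses(responses=out)


def clahe_enhance(
    texture: np.ndarray, clip_limit: float = 0.01, tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of a texture map.

    The input is min-max normalized to [0, 1] first; a constant input is
    returned unchanged (as zeros after normalization convention: constant
    maps have no contrast to equalize, so the constant is preserved).
    """
    texture = np.asarray(texture, dtype=np.float64)
    lo, hi = float(texture.min()), float(texture.max())
    if hi - lo <= 1e-15:
        return texture.copy()
    norm = (texture - lo) / (hi - lo)
    kernel_size = (
        max(texture.shape[0] // tiles[0], 1),
        max(texture.shape[1] // tiles[1], 1),
    )
    return equalize_adapthist(norm, kernel_size=kernel_size, clip_limit=clip_limit)
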