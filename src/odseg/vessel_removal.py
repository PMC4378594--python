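"""Vessel erasure inside the ROI: diffusion inpainting, closing, mean fill.

Diffusion (harmonic) inpainting is the preferred operator: masked pixels are
replaced by the solution of the discrete Laplace equation with Dirichlet
data from the mask boundary, which blends vessels away without inventing
texture. Grayscale closing and neighborhood-mean replacement are provided as
the classical alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import cg
from skimage.morphology import closing, disk

log = logging.getLogger(__name__)

__all__ = [
    "InpaintConfig",
    "inpaint_diffusion",
    "remove_vessels_closing",
    "remove_vessels_mean",
]


@dataclass(frozen=True)
class InpaintConfig:
    """Harmonic-inpainting controls.

    mask_dilation widens the vessel mask to cover edge halos; tolerance is
    the relative residual at which the Laplace solve stops (in units of the
    boundary-data scale); max_iterations bounds the solver.
    """

    mask_dilation: int = 2
    tolerance: float = 1e-8
    max_iterations: int = 5000

    def validate(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.mask_dilation < 0:
            raise ValueError("mask_dilation must be >= 0")


def _solve_laplace(channel: np.ndarray, mask: np.ndarray, cfg: InpaintConfig) -> np.ndarray:
    """Replace ``mask`` pixels of one channel by the harmonic interpolant.

    The 5-point Laplace system over the unknown pixels (Dirichlet data =
    surrounding known pixels; image borders treated as reflecting) is solved
    by conjugate gradients to cfg.tolerance.
    """
    h, w = channel.shape
    idx_map = -np.ones(channel.shape, dtype=np.int64)
    unknown = np.flatnonzero(mask)
    idx_map.flat[unknown] = np.arange(unknown.size)
    rows_u, cols_u = np.unravel_index(unknown, channel.shape)

    data, rows, cols = [], [], []
    b = np.zeros(unknown.size, dtype=np.float64)
    degree = np.zeros(unknown.size, dtype=np.float64)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nr, nc = rows_u + dr, cols_u + dc
        inside = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        # reflecting border: an out-of-image neighbor simply drops out
        degree += inside
        n_idx = np.full(unknown.size, -1, dtype=np.int64)
        n_idx[inside] = idx_map[nr[inside], nc[inside]]
        is_unknown = n_idx >= 0
        rows.append(np.nonzero(is_unknown)[0])
        cols.append(n_idx[is_unknown])
        data.append(-np.ones(is_unknown.sum()))
        known = inside & ~is_unknown
        np.add.at(b, np.nonzero(known)[0], channel[nr[known], nc[known]])
    rows.append(np.arange(unknown.size))
    cols.append(np.arange(unknown.size))
    data.append(degree)
    a_mat = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(unknown.size, unknown.size),
    )
    x0 = np.full(unknown.size, channel[~mask].mean() if (~mask).any() else 0.0)
    x, info = cg(a_mat, b, x0=x0, rtol=cfg.tolerance, maxiter=cfg.max_iterations)
    if info > 0:
        log.warning("inpainting CG stopped at max_iterations=%d", cfg.max_iterations)
    out = channel.copy()
    out.flat[unknown] = x
    return out


def inpaint_diffusion(
    image: np.ndarray, mask: np.ndarray, cfg: InpaintConfig = InpaintConfig()
) -> np.ndarray:
    """Diffusion-inpaint ``mask`` pixels of a gray or RGB image.

    Pixels outside the (dilated) mask are untouched bit-exactly; inpainted
    values obey the discrete maximum principle (they lie within the range of
    the surrounding boundary data).
    """
    cfg.validate()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match the image")
    if not mask.any():
        return image.copy()
    if cfg.mask_dilation > 0:
        mask = ndi.binary_dilation(mask, structure=disk(cfg.mask_dilation))
    if mask.all():
        raise ValueError("mask covers the entire image; no boundary data to diffuse")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return _solve_laplace(image, mask, cfg)
    return np.stack(
        [_solve_laplace(image[..., ch], mask, cfg) for ch in range(image.shape[-1])],
        axis=-1,
    )


def remove_vessels_closing(image: np.ndarray, se_radius: int = 15) -> np.ndarray:
    """Grayscale morphological closing with a disc structuring element.

    Fills dark structures thinner than the element (vessels) without a
    vessel mask; extensive (output >= input pointwise).
    """
    if image.ndim != 2:
        raise ValueError("closing operates on a single channel")
    return closing(np.asarray(image, dtype=np.float64), disk(se_radius))


def remove_vessels_mean(image: np.ndarray, mask: np.ndarray, window: int = 31) -> np.ndarray:
    """Replace masked pixels by the mean of unmasked pixels in their window.

    The window is clipped at image borders; if a neighborhood contains no
    unmasked pixel the window is doubled (plus one, to stay odd) until one
    is found.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match the image")
    out = image.copy()
    todo = mask.copy()
    known = np.where(mask, 0.0, image)
    known_cnt = (~mask).astype(np.float64)
    w = window
    max_dim = 2 * max(image.shape) + 1
    while todo.any():
        sums = ndi.uniform_filter(known, w, mode="constant", cval=0.0) * (w * w)
        cnts = ndi.uniform_filter(known_cnt, w, mode="constant", cval=0.0) * (w * w)
        fillable = todo & (cnts > 0.5)
        out[fillable] = sums[fillable] / cnts[fillable]
        todo &= ~fillable
        w = 2 * w + 1
        if todo.any() and w > max_dim:
            raise ValueError("mask covers the entire image; nothing to average")
    return out
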