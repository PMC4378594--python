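"""Independent brute-force reference implementations used by the tests.

Every function here is written as plain per-pixel loops over the defining
formula, deliberately ignoring the vectorized/FFT paths of the package, so
agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import circle_perimeter


def pearson_score_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct double-loop Pearson correlation over every valid placement."""
    ih, iw = image.shape
    th, tw = template.shape
    t = template - template.mean()
    t_ss = float((t**2).sum())
    out = np.zeros((ih - th + 1, iw - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = image[i : i + th, j : j + tw]
            f = win - win.mean()
            denom = np.sqrt((f**2).sum() * t_ss)
            out[i, j] = (f * t).sum() / denom if denom > 0 else 0.0
    return out


def hough_accumulate(edges: np.ndarray, radii) -> tuple[float, int, tuple[int, int]]:
    """Explicit vote loop + 3x3 box mean + argmax with the tie-break rules.

    Returns (score, radius, center) with ties broken toward the smallest
    radius, then row-major order.
    """
    h, w = edges.shape
    best = None
    for r in sorted(set(int(v) for v in radii)):
        offs = sorted(set(zip(*circle_perimeter(0, 0, r))))  # distinct perimeter pixels
        acc = np.zeros((h, w))
        for er, ec in np.argwhere(edges):
            for dr, dc in offs:
                cr, cc = er - dr, ec - dc
                if 0 <= cr < h and 0 <= cc < w:
                    acc[cr, cc] += 1
        sm = np.zeros_like(acc)
        for i in range(h):
            for j in range(w):
                tot = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if 0 <= i + di < h and 0 <= j + dj < w:
                            tot += acc[i + di, j + dj]
                sm[i, j] = tot / 9.0
        idx = int(np.argmax(sm))
        val = float(sm.flat[idx])
        if best is None or val > best[0]:
            best = (val, r, np.unravel_index(idx, sm.shape))
    return best


def neighborhood_mean_fill(image: np.ndarray, mask: np.ndarray, window: int) -> np.ndarray:
    """Loop reference of masked-pixel replacement by unmasked window mean."""
    h, w = image.shape
    out = image.copy()
    for r, c in np.argwhere(mask):
        win = window
        while True:
            k = win // 2
            vals = [
                image[i, j]
                for i in range(max(r - k, 0), min(r + k + 1, h))
                for j in range(max(c - k, 0), min(c + k + 1, w))
                if not mask[i, j]
            ]
            if vals:
                out[r, c] = float(np.mean(vals))
                break
            win = 2 * win + 1
    return out


def dice_sets(a: np.ndarray, b: np.ndarray) -> float:
    """Dice via explicit pixel loops."""
    na = nb = ni = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            na += bool(a[i, j])
            nb += bool(b[i, j])
            ni += bool(a[i, j]) and bool(b[i, j])
    return 1.0 if na + nb == 0 else 2.0 * ni / (na + nb)


def point_in_polygon(r: float, c: float, pts: np.ndarray) -> bool:
    """Even-odd crossing-number test for one point (ray toward +col)."""
    inside = False
    n = len(pts)
    for k in range(n):
        r1, c1 = pts[k]
        r2, c2 = pts[(k + 1) % n]
        if (r1 > r) != (r2 > r):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_int:
                inside = not inside
    return inside


def rasterize_polygon(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Brute-force even-odd rasterization over all pixel centers."""
    out = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            out[i, j] = point_in_polygon(float(i), float(j), pts)
    return out
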