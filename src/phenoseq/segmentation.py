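"""Plant segmentation from top-view RGB frames.

The pipeline follows the classic seeded-GrabCut recipe for rosettes on soil:

1. convert RGB to CIE L*a*b*; green vegetation separates from brown soil in
   the a* (green-red) and b* (blue-yellow) opponent channels;
2. per-channel Otsu thresholding, then a morphological dilation added onto the
   binary mask, producing a 3-level ("trinary") mask per channel — 0 definite
   background, 1 probable (the dilation ring protecting faded leaf borders),
   2 foreground;
3. combine the two trinary masks into one 4-level GrabCut seed mask;
4. mask-initialised GrabCut with the bounding box as large as the image,
   followed by morphological opening and closing.

Level conventions of the 4-level mask: 0 definite background, 1 definite
foreground, 2 probable background, 3 probable foreground.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab
from skimage.morphology import dilation, opening, closing, disk

from . import _grabcut

__all__ = [
    "DEF_BG", "DEF_FG", "PROB_BG", "PROB_FG",
    "otsu_threshold", "histogram_256", "channel_trinary_mask", "combine_masks",
    "grabcut_refine", "segment_plant", "color_correct", "iou",
]

DEF_BG, DEF_FG, PROB_BG, PROB_FG = 0, 1, 2, 3

#: Trinary-pair -> quaternary level lookup (row: a-channel value, col: b-channel value)
_COMBINE_TABLE = np.array([
    [DEF_BG, PROB_BG, PROB_FG],
    [PROB_BG, PROB_BG, PROB_FG],
    [PROB_FG, PROB_FG, DEF_FG],
], dtype=np.uint8)


def histogram_256(channel: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit single-channel image."""
    ch = np.asarray(channel)
    if ch.min() < 0 or ch.max() > 255:
        raise ValueError("channel must contain 8-bit values in [0, 255]")
    return np.bincount(ch.astype(np.int64).ravel(), minlength=256)[:256]


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on an intensity histogram.

    Returns the level ``t`` maximising the between-class variance of the split
    ``{<= t}`` vs ``{> t}``; ties break to the smallest level.  A histogram
    with a single nonzero bin returns that bin's level (degenerate split).
    """
    h = np.asarray(hist, dtype=np.float64)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be a 1-D array with >= 2 bins")
    if h.sum() <= 0:
        raise ValueError("histogram is empty")
    nz = np.flatnonzero(h)
    if nz.size == 1:
        return int(nz[0])
    levels = np.arange(h.size)
    p = h / h.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(h.size)
    sigma_b[valid] = (mu_t * w0[valid] - mu[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximiser


def between_class_variance(hist: np.ndarray, t: int) -> float:
    """Between-class variance of the Otsu split at threshold ``t``."""
    h = np.asarray(hist, dtype=np.float64)
    p = h / h.sum()
    levels = np.arange(h.size)
    w0 = p[: t + 1].sum()
    w1 = 1.0 - w0
    if w0 <= 0 or w1 <= 0:
        return 0.0
    mu0 = (p[: t + 1] * levels[: t + 1]).sum() / w0
    mu1 = (p[t + 1:] * levels[t + 1:]).sum() / w1
    return float(w0 * w1 * (mu0 - mu1) ** 2)


def _default_selem(shape: tuple[int, int], base_radius: int) -> np.ndarray:
    # radii are quoted at a 256 px canvas and scaled proportionally
    radius = max(1, round(base_radius * min(shape) / 256))
    return disk(radius)


def channel_trinary_mask(
    channel: np.ndarray,
    foreground_polarity: str,
    selem: np.ndarray | None = None,
) -> np.ndarray:
    """Otsu binarisation plus a dilation ring, as a 3-level mask.

    ``foreground_polarity`` selects which side of the Otsu threshold is
    candidate plant: ``"low"`` (a* channel: green is negative) or ``"high"``
    (b* channel: green-yellow is positive).  The binary mask B is dilated to D
    and the two are summed: 2 on B (foreground), 1 on the ring D \\ B
    (probable), 0 elsewhere.  A constant channel carries no plant evidence and
    yields all zeros.
    """
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise ValueError("channel must be single-channel (2-D)")
    if foreground_polarity not in ("low", "high"):
        raise ValueError("foreground_polarity must be 'low' or 'high'")
    out = np.zeros(ch.shape, dtype=np.uint8)
    if ch.min() == ch.max():
        return out
    t = otsu_threshold(histogram_256(ch))
    binary = (ch <= t) if foreground_polarity == "low" else (ch > t)
    if selem is None:
        selem = _default_selem(ch.shape, 5)
    dilated = dilation(binary, selem)
    return (binary.astype(np.uint8) + dilated.astype(np.uint8))


def combine_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Combine the a*- and b*-channel trinary masks into the 4-level seed.

    Element-wise rule: both-0 -> definite background; both-2 -> definite
    foreground; any 2 against 0/1 -> probable foreground; remaining 0/1
    combinations -> probable background.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError("trinary masks must share shape")
    for m in (a, b):
        if not np.isin(m, (0, 1, 2)).all():
            raise ValueError("trinary masks must only contain {0, 1, 2}")
    return _COMBINE_TABLE[a.astype(np.intp), b.astype(np.intp)]


def grabcut_refine(
    rgb: np.ndarray,
    seed: np.ndarray,
    iterations: int = 5,
    opening_radius: int = 2,
    gamma: float = 50.0,
) -> np.ndarray:
    """GrabCut from the 4-level seed, then morphological opening and closing.

    The definite seed levels are honoured: definite-foreground pixels stay
    foreground and definite-background pixels stay background in the output.
    Raises ``ValueError`` when the seed holds no foreground evidence at all.
    """
    seed = np.asarray(seed)
    if not ((seed == DEF_FG) | (seed == PROB_FG)).any():
        raise ValueError("seed mask contains no foreground evidence")
    mask = _grabcut.grabcut(rgb, seed, iterations=iterations, gamma=gamma)
    selem = _default_selem(seed.shape, opening_radius)
    mask = closing(opening(mask, selem), selem)
    mask |= seed == DEF_FG
    mask &= seed != DEF_BG
    return mask


def segment_plant(
    rgb: np.ndarray,
    iterations: int = 5,
    min_bimodality: float = 0.5,
    selem: np.ndarray | None = None,
) -> np.ndarray:
    """Full segmentation pipeline on one RGB frame; returns a boolean mask.

    ``min_bimodality`` is a floor on the a*-channel between-class variance at
    the Otsu threshold (in 8-bit-level^2 units): below it the frame is treated
    as plant-free (an Otsu split of a unimodal soil histogram is meaningless),
    and an empty mask is returned instead of an error.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    lab = rgb2lab(rgb)
    a8 = np.clip(np.round(lab[:, :, 1] + 128), 0, 255).astype(np.uint8)
    b8 = np.clip(np.round(lab[:, :, 2] + 128), 0, 255).astype(np.uint8)

    empty = np.zeros(rgb.shape[:2], dtype=bool)
    if a8.min() == a8.max():
        return empty
    hist_a = histogram_256(a8)
    if between_class_variance(hist_a, otsu_threshold(hist_a)) < min_bimodality:
        return empty

    tri_a = channel_trinary_mask(a8, "low", selem=selem)
    tri_b = channel_trinary_mask(b8, "high", selem=selem)
    quat = combine_masks(tri_a, tri_b)
    if not ((quat == DEF_FG) | (quat == PROB_FG)).any():
        return empty
    return grabcut_refine(rgb, quat, iterations=iterations)


def color_correct(
    image: np.ndarray,
    observed_patch_colors: np.ndarray,
    reference_patch_colors: np.ndarray,
) -> np.ndarray:
    """Affine colour correction fitted on colour-card patches.

    Least-squares fit of a 3x3 matrix plus offset mapping observed patch RGB
    values onto their references, applied to the whole image with clipping.
    Requires at least 4 non-degenerate patch pairs.
    """
    obs = np.asarray(observed_patch_colors, dtype=np.float64)
    ref = np.asarray(reference_patch_colors, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[1] != 3 or obs.shape != ref.shape:
        raise ValueError("patch arrays must be matching (n, 3)")
    if len(obs) < 4:
        raise ValueError("need at least 4 patch pairs")
    design = np.hstack([obs, np.ones((len(obs), 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("patch set is rank-deficient; cannot fit affine transform")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    img = np.asarray(image, dtype=np.float64)
    flat = img.reshape(-1, 3) @ coef[:3] + coef[3]
    out = np.clip(flat.reshape(img.shape), 0, 255)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.round(out).astype(np.asarray(image).dtype)
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 when both empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
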